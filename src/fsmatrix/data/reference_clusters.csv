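type_id,cluster
playpens,1
prams,1
baby_mattress,1
baby_changing_mat,1
floor_cushion,2
car_seat,2
child_trailers_strollers,2
separate_baby_upholstery,2
bean_bag,2
outdoor_furniture,2
side_rails,2
seat_pad,2
outdoor_furniture_separate_upholstery,2
light_up_childrens_cushion,3
baby_products_with_seat,3
carry_cots,3
baby_nests,3
pillow,3
bassinet,3
play_mat,3
padded_foot_stools,4
footboard,4
pet_beds,4
headboard,5
living_aids,5
upholstered_bed_base,5
armchairs,5
divan,outlier
loose_stretch_covers,outlier
scatter_cushion,outlier
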