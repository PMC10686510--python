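type_id,display_name,small_child_product,notes
armchairs,Armchairs,false,
baby_changing_mat,Baby changing mat,true,
baby_mattress,Baby mattress,true,
baby_nests,Baby nests,true,
baby_products_with_seat,Baby products with seat,true,
bassinet,Bassinet,true,
bean_bag,Bean bag,false,
car_seat,Car seat,true,
carry_cots,Carry cots,true,
child_trailers_strollers,Child trailers and strollers,true,
divan,Divan,false,
floor_cushion,Floor cushion,false,
footboard,Footboard,false,
headboard,Headboard,false,
light_up_childrens_cushion,Light-up children's cushion,true,
living_aids,Living aids,false,
loose_stretch_covers,Loose and stretch covers,false,
outdoor_furniture,Outdoor furniture,false,
outdoor_furniture_separate_upholstery,Outdoor furniture separate upholstery,false,
padded_foot_stools,Padded foot stools,false,
pet_beds,Pet beds,false,
pillow,Pillow,false,
play_mat,Play mat,true,
playpens,Playpens,true,
prams,Prams,true,
scatter_cushion,Scatter cushion,false,
seat_pad,Seat pad,false,
separate_baby_upholstery,Separate baby upholstery,true,
side_rails,Side rails,true,
upholstered_bed_base,Upholstered bed base,false,
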