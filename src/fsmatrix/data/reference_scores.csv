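type_id,injury_low,injury_high,injury_mean,exposure_low,exposure_high,exposure_mean
armchairs,2.00,4.63,3.31,1.80,3.00,2.40
baby_changing_mat,1.63,1.75,1.69,3.00,3.20,3.10
baby_mattress,1.63,1.75,1.69,3.20,3.40,3.30
baby_nests,3.13,3.13,3.13,3.20,3.40,3.30
baby_products_with_seat,2.38,3.38,2.88,3.40,3.60,3.50
bassinet,2.38,2.63,2.50,3.20,4.00,3.60
bean_bag,1.63,3.38,2.50,2.40,3.40,2.90
car_seat,1.88,2.00,1.94,3.40,3.40,3.40
carry_cots,3.13,3.50,3.31,3.40,3.60,3.50
child_trailers_strollers,1.00,2.50,1.75,3.00,3.60,3.30
divan,1.75,1.75,1.75,1.60,1.60,1.60
floor_cushion,2.00,1.75,1.88,3.40,3.20,3.30
footboard,2.38,2.63,2.50,1.80,2.00,1.90
headboard,2.63,3.88,3.25,2.00,2.40,2.20
light_up_childrens_cushion,2.75,2.75,2.75,3.60,3.60,3.60
living_aids,2.38,3.63,3.00,2.00,3.20,2.60
loose_stretch_covers,2.75,4.00,3.38,2.80,3.80,3.30
outdoor_furniture,1.38,2.75,2.06,1.60,3.40,2.50
outdoor_furniture_separate_upholstery,1.88,2.75,2.31,2.60,2.80,2.70
padded_foot_stools,2.63,2.75,2.69,1.80,2.40,2.10
pet_beds,1.75,3.00,2.38,1.60,2.20,1.90
pillow,2.00,2.88,2.44,4.20,3.20,3.70
play_mat,1.75,3.50,2.63,3.20,3.60,3.40
playpens,1.88,1.75,1.81,3.80,4.00,3.90
prams,1.38,1.75,1.56,3.40,3.60,3.50
scatter_cushion,2.75,3.00,2.88,3.00,3.20,3.10
seat_pad,2.00,2.88,2.44,2.40,2.80,2.60
separate_baby_upholstery,2.50,1.75,2.13,3.20,3.20,3.20
side_rails,1.38,3.00,2.19,3.40,2.20,2.80
upholstered_bed_base,2.75,3.75,3.25,2.00,3.00,2.50
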