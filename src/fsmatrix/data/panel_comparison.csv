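type_id,variant,evaluator,contact,junction_count,ornateness,reactive_capacity
armchair,high,consensus,5,3,3,5
armchair,high,panel_1,4,3,1,5
armchair,high,panel_2,4,3,2,4
armchair,high,panel_3,4,5,4,4
armchair,low,consensus,3,1,2,2
armchair,low,panel_1,1,1,1,1
armchair,low,panel_2,2,1,2,1
armchair,low,panel_3,3,1,3,1
headboard,high,consensus,4,3,3,4
headboard,high,panel_1,3,1,3,3
headboard,high,panel_2,2,0,2,2
headboard,high,panel_3,4,0,5,1
headboard,low,consensus,3,1,1,4
headboard,low,panel_1,1,1,1,3
headboard,low,panel_2,2,0,1,2
headboard,low,panel_3,4,0,3,1
pushchair,high,consensus,1,12,4,3
pushchair,high,panel_1,2,6,3,1
pushchair,high,panel_2,2,6,4,2
pushchair,high,panel_3,2,6,5,
pushchair,low,consensus,1,3,3,3
pushchair,low,panel_1,2,3,3,1
pushchair,low,panel_2,2,1,3,2
pushchair,low,panel_3,3,3,2,
pet_bed,high,consensus,4,3,2,3
pet_bed,high,panel_1,1,1,1,1
pet_bed,high,panel_2,1,1,1,1
pet_bed,high,panel_3,2,1,4,2
pet_bed,low,consensus,3,0,1,2
pet_bed,low,panel_1,1,0,1,1
pet_bed,low,panel_2,0,0,0,1
pet_bed,low,panel_3,3,4,3,2
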