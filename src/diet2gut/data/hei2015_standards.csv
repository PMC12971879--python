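# HEI-2015 component scoring standards. Densities are per 1,000 kcal unless the
# basis says otherwise (ratio = (MUFA+PUFA)/SFA; pct_energy = % of total energy).
# For adequacy components, std_max is the density at/above which the component
# earns full points and std_min the density scoring zero. For moderation
# components the direction reverses: full points at/below std_max, zero at/above
# std_min. Component maxima sum to 100.
component,type,basis,source,max_points,std_max,std_min
total_fruits,adequacy,per_1000kcal,total_fruits,5,0.8,0.0
whole_fruits,adequacy,per_1000kcal,whole_fruits,5,0.4,0.0
total_vegetables,adequacy,per_1000kcal,total_vegetables,5,1.1,0.0
greens_and_beans,adequacy,per_1000kcal,greens_beans,5,0.2,0.0
whole_grains,adequacy,per_1000kcal,whole_grains,10,1.5,0.0
dairy,adequacy,per_1000kcal,dairy,10,1.3,0.0
total_protein_foods,adequacy,per_1000kcal,total_protein,5,2.5,0.0
seafood_and_plant_proteins,adequacy,per_1000kcal,seafood_plant_protein,5,0.8,0.0
fatty_acids,adequacy,ratio,fatty_acid_ratio,10,2.5,1.2
refined_grains,moderation,per_1000kcal,refined_grains,10,1.8,4.3
sodium,moderation,per_1000kcal,sodium_g,10,1.1,2.0
added_sugars,moderation,pct_energy,added_sugars_pct,10,6.5,26.0
saturated_fats,moderation,pct_energy,saturated_fat_pct,10,8.0,16.0
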