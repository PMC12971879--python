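# Diet quality index rubric: variety, adequacy, moderation and balance
# components, each scored on a 0-3, 0-5 or 0-6 point scale; maxima sum to 100.
# Threshold lists are semicolon-separated with one threshold per attainable
# point: for direction=higher_better (ascending thresholds) a subject earns one
# point per threshold their value meets or exceeds; for lower_better
# (descending) one point per threshold their value is at or below. Sources
# prefixed "derived:" are computed from the intake/food-group tables (see
# diet_indices docs). The component set and cut-points are a reconstruction
# assembled for this package in the spirit of serving/nutrient-based
# 100-point diet-quality rubrics.
component,category,source,direction,max_points,thresholds
food_group_variety,variety,derived:food_group_variety,higher_better,6,1;2;3;4;5;6
protein_source_variety,variety,derived:protein_source_variety,higher_better,3,1;2;3
vegetables,adequacy,vegetables,higher_better,6,0.5;1;1.5;2;2.5;3
fruit_nuts,adequacy,fruit_nuts,higher_better,6,0.5;1;1.5;2;2.5;3
cereals,adequacy,cereals,higher_better,6,1;2;3;4;5;6
legumes,adequacy,legumes,higher_better,3,0.15;0.3;0.5
fish_seafood,adequacy,fish_seafood,higher_better,3,0.2;0.4;0.6
fiber,adequacy,fiber,higher_better,5,10;15;20;25;30
protein,adequacy,protein,higher_better,5,40;50;60;70;80
iron,adequacy,iron,higher_better,5,6;9;12;15;18
calcium,adequacy,calcium,higher_better,5,400;600;800;1000;1200
vitamin_c,adequacy,vitamin_c,higher_better,5,30;45;60;75;90
total_fat_pct,moderation,derived:total_fat_pct,lower_better,6,40;37;34;31;28;25
saturated_fat_pct,moderation,derived:saturated_fat_pct,lower_better,6,15;13;11;10;9;8
cholesterol,moderation,cholesterol,lower_better,6,450;400;350;300;250;200
sodium,moderation,sodium,lower_better,6,4000;3600;3200;2800;2400;2000
empty_calorie_foods,moderation,empty_calorie_foods,lower_better,6,2.5;2;1.5;1;0.5;0.25
macronutrient_balance,balance,derived:carb_pct_dev,lower_better,6,25;20;15;10;7.5;5
fatty_acid_balance,balance,derived:fat_ratio_dev,lower_better,6,2;1.6;1.2;0.9;0.6;0.3
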