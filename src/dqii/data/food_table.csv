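food_id,name,energy_kcal,protein_g,carbohydrate_g,total_fat_g,saturated_fat_g,mufa_g,pufa_g,cholesterol_mg,sodium_mg,fibre_g,iron_mg,calcium_mg,vitamin_c_mg,variety_group,protein_source,empty_calorie,serving_size_g
spinach_raw,"Spinach, raw",20.8,2.9,1.4,0.4,0.06,0.01,0.17,0,79,2.2,2.7,99,28.1,vegetables,none,False,80
broccoli_raw,"Broccoli, raw",30.8,2.8,4.0,0.4,0.04,0.01,0.04,0,33,2.6,0.7,47,89.2,vegetables,none,False,80
carrot_raw,"Carrot, raw",32.6,0.9,6.8,0.2,0.03,0.01,0.1,0,69,2.8,0.3,33,5.9,vegetables,none,False,80
tomato_raw,"Tomato, raw",16.2,0.9,2.7,0.2,0.03,0.03,0.08,0,5,1.2,0.3,10,13.7,vegetables,none,False,80
red_pepper_raw,"Sweet red pepper, raw",22.3,1.0,3.9,0.3,0.06,0.01,0.16,0,4,2.1,0.4,7,127.7,vegetables,none,False,80
apple_raw,"Apple, with skin",48.6,0.3,11.4,0.2,0.03,0.01,0.05,0,1,2.4,0.1,6,4.6,fruits,none,False,120
banana_raw,"Banana, raw",87.9,1.1,20.2,0.3,0.11,0.03,0.07,0,1,2.6,0.3,5,8.7,fruits,none,False,120
orange_raw,"Orange, raw",42.1,0.9,9.4,0.1,0.02,0.02,0.03,0,0,2.4,0.1,40,53.2,fruits,none,False,120
strawberries_raw,"Strawberries, raw",28.3,0.7,5.7,0.3,0.02,0.04,0.16,0,1,2.0,0.4,16,58.8,fruits,none,False,120
brown_rice_cooked,"Brown rice, cooked",103.3,2.6,21.2,0.9,0.18,0.33,0.32,0,5,1.8,0.4,10,0,grains,none,False,80
rolled_oats_dry,"Rolled oats, dry",352.5,16.9,55.7,6.9,1.22,2.18,2.54,0,2,10.6,4.7,54,0,grains,none,False,40
wholemeal_bread,Wholemeal bread,218.6,13.0,34.0,3.4,0.7,0.6,1.4,0,450,7.0,2.5,107,0,grains,none,False,35
quinoa_cooked,"Quinoa, cooked",108.7,4.4,18.5,1.9,0.23,0.53,1.08,0,7,2.8,1.5,17,0,grains,none,False,90
pasta_cooked,"Wholewheat pasta, cooked",147.7,5.8,29.1,0.9,0.17,0.13,0.32,0,1,1.8,0.5,7,0,grains,none,False,90
chicken_breast_grilled,"Chicken breast, grilled",156.4,31.0,0.0,3.6,1.01,1.24,0.77,85,74,0,1.0,15,0,meat_poultry_fish_egg,poultry,False,85
turkey_breast_roast,"Turkey breast, roast",125.0,29.0,0.0,1.0,0.3,0.2,0.3,80,63,0,1.1,12,0,meat_poultry_fish_egg,poultry,False,85
beef_sirloin_lean,"Beef sirloin, lean, cooked",180.0,27.0,0.0,8.0,3.1,3.4,0.35,90,56,0,2.9,18,0,meat_poultry_fish_egg,meat,False,85
salmon_atlantic_cooked,"Atlantic salmon, cooked",196.0,22.0,0.0,12.0,2.5,4.4,3.8,63,61,0,0.3,15,0,meat_poultry_fish_egg,fish,False,85
cod_cooked,"Cod, cooked",82.3,19.0,0.0,0.7,0.14,0.1,0.24,55,78,0,0.4,14,0,meat_poultry_fish_egg,fish,False,85
egg_boiled,"Egg, whole, boiled",150.2,12.6,1.1,10.6,3.27,4.08,1.41,373,124,0,1.2,50,0,meat_poultry_fish_egg,eggs,False,50
greek_yoghurt_nonfat,"Greek yoghurt, non-fat",58.8,10.2,3.6,0.4,0.12,0.1,0.05,5,36,0,0.1,110,0,dairy_beans,dairy,False,170
milk_semi_skimmed,"Milk, semi-skimmed",49.0,3.4,4.8,1.8,1.1,0.5,0.1,8,44,0,0.0,120,0.5,dairy_beans,dairy,False,250
cottage_cheese,Cottage cheese,96.3,11.0,3.4,4.3,1.7,0.9,0.15,17,364,0,0.1,83,0,dairy_beans,dairy,False,110
cheddar_cheese,Cheddar cheese,402.2,25.0,1.3,33.0,21.0,9.4,0.94,105,621,0,0.7,721,0,dairy_beans,dairy,False,30
lentils_cooked,"Lentils, cooked",88.0,9.0,12.1,0.4,0.05,0.06,0.18,0,2,7.9,3.3,19,1.5,dairy_beans,beans,False,100
chickpeas_cooked,"Chickpeas, cooked",138.2,8.9,19.8,2.6,0.27,0.58,1.16,0,7,7.6,2.9,49,1.3,dairy_beans,beans,False,100
black_beans_cooked,"Black beans, cooked",100.1,8.9,15.0,0.5,0.14,0.05,0.23,0,1,8.7,2.1,27,0,dairy_beans,beans,False,100
olive_oil,Olive oil,900.0,0,0,100.0,14.0,75.0,11.0,0,0,0,0,0,0,other,none,False,14
sunflower_oil,Sunflower oil,900.0,0,0,100.0,11.0,22.0,67.0,0,0,0,0,0,0,other,none,False,14
coconut_oil,Coconut oil,900.0,0,0,100.0,90.0,8.0,2.0,0,0,0,0,0,0,other,none,False,14
white_sugar,White sugar,400.0,0,100.0,0,0,0,0,0,0,0,0,0,0,other,none,True,4
maltodextrin_powder,Maltodextrin powder,384.0,0,96.0,0,0,0,0,0,0,0,0,0,0,other,none,False,10
whey_protein_isolate,Whey protein isolate,372.5,90.0,2.0,0.5,0.2,0.15,0.15,5,50,0,0.2,120,0,other,none,False,30
inulin_fibre,Inulin fibre supplement,0,0,0,0,0,0,0,0,0,90.0,0,0,0,other,none,False,10
iron_premix,Iron fortification premix,0,0,0,0,0,0,0,0,0,0,1000.0,0,0,other,none,False,1
calcium_premix,Calcium fortification premix,0,0,0,0,0,0,0,0,0,0,0,10000.0,0,other,none,False,1
vitamin_c_powder,Vitamin C powder,0,0,0,0,0,0,0,0,0,0,0,0,50000.0,other,none,False,1
table_salt,Table salt,0,0,0,0,0,0,0,0,38700.0,0,0,0,0,other,none,False,1
cholesterol_concentrate,Cholesterol concentrate (synthetic test article),0,0,0,0,0,0,0,10000.0,0,0,0,0,0,other,none,False,1
water_still,Still water,0,0,0,0,0,0,0,0,0,0,0,0,0,other,none,False,250
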