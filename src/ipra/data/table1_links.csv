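food_code,basic_product,fraction
Sauce prepared from sauce powder,Sauce powder,0.18
Dishes containing sauce,Sauce powder,0.09
Pure meat seasoning,Meat seasoning,1.0
Dishes containing meat seasoning,Meat seasoning,0.03
Pure cake flour,Cake mix,1.0
Cakes containing flour,Cake mix,0.55
Noodle dishes,Instant noodles,0.03
Soup prepared from instant soup powder,Instant soup powder,0.06
Pure creamer,Coffee creamers,1.0
Drinks containing creamer,Coffee creamers,0.03
Pure bread crumbs,Rubs,1.0
Dishes containing bread crumbs,Rubs,0.1
Pure spice mix,International seasoning mixes,1.0
Dishes containing spice mix,International seasoning mixes,0.1
Dishes containing spice mix and a starch,International seasoning mixes,0.05
Pure pancake flour,Pancake mix,1.0
Pancakes containing pancake flour,Pancake mix,0.32
Drinks containing cappuccino creamer,Cappuccino creamer,0.03
Drinks prepared from soy shake,Soy shake,0.08
Vitamin C tablets pills and capsules,Vitamin C tablets,1.0
Multivitamin junior or kid tablets pills and capsules,Multivitamin Junior,1.0
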