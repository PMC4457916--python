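basic_product,measured_product,total_silica_mg_per_g,nanosilica_mg_per_g,nano_censored
Sauce powder,Mix for lasagna sauce,5.4,0.3,0
Sauce powder,Cheese sauce,6.6,,
Meat seasoning,Minced meat seasoning mix,2.6,0.2,0
Cake mix,Cake with icing,0.6,,
Instant noodles,Instant noodles tandoori,12.9,,
Instant noodles,Instant noodles chicken,5.8,,
Instant soup powder,Instant asparagus soup,0.6,0.2,0
Instant soup powder,Instant beef soup,0.6,,
Coffee creamers,Coffee creamer (brand a),5.1,1.0,0
Coffee creamers,Coffee creamer (brand b),4.9,,
Rubs,Spicy pepper rub,1.1,0.1,1
Rubs,Sweets sticky rub,6.0,0.4,0
Rubs,Steak house rub,4.3,0.2,0
Rubs,Roasted vegetable rub,4.9,0.6,0
Rubs,Sea food rub,4.7,0.5,0
International seasoning mixes,Burrito seasoning mix,7.1,0.3,0
International seasoning mixes,Taco seasoning mix,11.4,,
International seasoning mixes,Guacamole seasoning mix,5.8,,
International seasoning mixes,Nasi rames seasoning mix,6.2,,
Pancake mix,Pancake mix,2.8,0.1,1
Cappuccino creamer,Cappuccino foam creamer,4.9,,
Soy shake,Soy slim shake,3.4,,
Vitamin C tablets,Vitamin C,1.5,,
Multivitamin Junior,Multivitamins junior (brand a),13.7,,
Multivitamin Junior,Multivitamins junior (brand b),13.7,,
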