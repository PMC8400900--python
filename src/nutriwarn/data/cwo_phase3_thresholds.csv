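scope,nutrient,limit,unit,comparator,gate,label
food,energy,275,kcal,at_least,added_sugar|added_sodium|added_sat_fat,energy
food,total_sugar,10,g,at_least,added_sugar,sugar
food,sodium,400,mg,at_least,added_sodium,sodium
food,saturated_fat,4,g,at_least,added_sat_fat,saturated_fat
beverage,energy,70,kcal,at_least,added_sugar|added_sodium|added_sat_fat,energy
beverage,total_sugar,5,g,at_least,added_sugar,sugar
beverage,sodium,100,mg,at_least,added_sodium,sodium
beverage,saturated_fat,3,g,at_least,added_sat_fat,saturated_fat
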