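code,name,is_beverage,required_nutrients
1,Confectionary,false,total_fat;saturated_fat;total_sugar;sodium
2,"Cakes, sweet biscuits, pastries",false,total_fat;saturated_fat;total_sugar;added_sugar;sodium
3,Bread and bread products,false,total_fat;saturated_fat;total_sugar;sodium
4,Cereals,false,total_fat;saturated_fat;total_sugar;added_sugar;sodium
5A,"Potato, cereal, or starch-based (from roots, tuber, or legumes), and animal-based (from skin) foods",false,energy;total_fat;saturated_fat;total_sugar;sodium
5B,Processed nuts,false,total_fat;saturated_fat;total_sugar;sodium
5C,Fish-based foods,false,total_fat;saturated_fat;sodium
6A,Juices,true,energy;total_sugar
6B,Milk- and dairy-based drinks,true,total_fat;saturated_fat;total_sugar;sodium
6C,Water-based flavored drinks,true,energy;total_sugar
6D,"Coffee, coffee substitutes, tea, herbal infusions",true,energy;total_sugar
6E,"Cereal, grain, tree nut-based beverages",true,total_fat;total_sugar;sodium
7,Frozen dairy-based desserts and edible ices,false,total_fat;saturated_fat;total_sugar;added_sugar;sodium
8,Curded dairy-based desserts,false,total_fat;saturated_fat;total_sugar;added_sugar;sodium
9,Cheese and analogues,false,total_fat;saturated_fat;sodium
10,Composite foods (prepared foods),false,energy;total_fat;saturated_fat;total_sugar;sodium
11,"Fats and oils, and fat emulsions",false,saturated_fat;sodium
12,"Pasta, noodles, and similar products",false,total_fat;saturated_fat;total_sugar;sodium
13,"Fresh and frozen meat, poultry, game, fish, and seafood products",false,total_fat;saturated_fat;sodium
14A,"Processed meat, poultry, and game products",false,total_fat;saturated_fat;sodium
14B,Processed fish and seafood products,false,total_fat;saturated_fat;sodium
15,"Fresh and frozen fruits and vegetables, and legumes",false,total_sugar;sodium
16,Processed fruits and vegetables,false,total_fat;total_sugar;sodium
17,Solid-form soybean products,false,total_fat;saturated_fat;sodium
18,"Sauces, dips, and dressings",false,total_fat;saturated_fat;total_sugar;sodium
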