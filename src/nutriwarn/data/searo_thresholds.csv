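scope,nutrient,limit,unit,comparator,gate,label
1,total_fat,5,g,greater_than,,fat
1,saturated_fat,3,g,greater_than,,saturated_fat
1,total_sugar,6,g,greater_than,,sugar
1,sodium,50,mg,greater_than,,sodium
2,total_fat,10,g,greater_than,,fat
2,saturated_fat,4,g,greater_than,,saturated_fat
2,total_sugar,15,g,greater_than,,sugar
2,added_sugar,10,g,greater_than,,sugar
2,sodium,120,mg,greater_than,,sodium
3,total_fat,7,g,greater_than,,fat
3,saturated_fat,3,g,greater_than,,saturated_fat
3,total_sugar,5,g,greater_than,,sugar
3,sodium,450,mg,greater_than,,sodium
4,total_fat,10,g,greater_than,,fat
4,saturated_fat,4,g,greater_than,,saturated_fat
4,total_sugar,12.5,g,greater_than,,sugar
4,added_sugar,7.5,g,greater_than,,sugar
4,sodium,400,mg,greater_than,,sodium
5A,energy,350,kcal,greater_than,,energy
5A,total_fat,15,g,greater_than,,fat
5A,saturated_fat,5,g,greater_than,,saturated_fat
5A,total_sugar,10,g,greater_than,,sugar
5A,sodium,500,mg,greater_than,,sodium
5B,total_fat,35,g,greater_than,,fat
5B,saturated_fat,5,g,greater_than,,saturated_fat
5B,total_sugar,10,g,greater_than,,sugar
5B,sodium,100,mg,greater_than,,sodium
5C,total_fat,10,g,greater_than,,fat
5C,saturated_fat,4,g,greater_than,,saturated_fat
5C,sodium,400,mg,greater_than,,sodium
6A,energy,60,kcal,greater_than,,energy
6A,total_sugar,5,g,greater_than,,sugar
6B,total_fat,2.5,g,greater_than,,fat
6B,saturated_fat,2,g,greater_than,,saturated_fat
6B,total_sugar,6,g,greater_than,,sugar
6B,sodium,100,mg,greater_than,,sodium
6C,energy,50,kcal,greater_than,,energy
6C,total_sugar,5,g,greater_than,,sugar
6D,energy,40,kcal,greater_than,,energy
6D,total_sugar,5,g,greater_than,,sugar
6E,total_fat,2.5,g,greater_than,,fat
6E,total_sugar,5,g,greater_than,,sugar
6E,sodium,100,mg,greater_than,,sodium
7,total_fat,8,g,greater_than,,fat
7,saturated_fat,5,g,greater_than,,saturated_fat
7,total_sugar,10,g,greater_than,,sugar
7,added_sugar,8,g,greater_than,,sugar
7,sodium,100,mg,greater_than,,sodium
8,total_fat,5,g,greater_than,,fat
8,saturated_fat,3,g,greater_than,,saturated_fat
8,total_sugar,10,g,greater_than,,sugar
8,added_sugar,8,g,greater_than,,sugar
8,sodium,100,mg,greater_than,,sodium
9,total_fat,20,g,greater_than,,fat
9,saturated_fat,10,g,greater_than,,saturated_fat
9,sodium,500,mg,greater_than,,sodium
10,energy,225,kcal,greater_than,,energy
10,total_fat,10,g,greater_than,,fat
10,saturated_fat,4,g,greater_than,,saturated_fat
10,total_sugar,10,g,greater_than,,sugar
10,sodium,400,mg,greater_than,,sodium
11,saturated_fat,20,g,greater_than,,saturated_fat
11,sodium,400,mg,greater_than,,sodium
12,total_fat,10,g,greater_than,,fat
12,saturated_fat,4,g,greater_than,,saturated_fat
12,total_sugar,10,g,greater_than,,sugar
12,sodium,400,mg,greater_than,,sodium
13,total_fat,10,g,greater_than,,fat
13,saturated_fat,4,g,greater_than,,saturated_fat
13,sodium,300,mg,greater_than,,sodium
14A,total_fat,20,g,greater_than,,fat
14A,saturated_fat,7,g,greater_than,,saturated_fat
14A,sodium,500,mg,greater_than,,sodium
14B,total_fat,10,g,greater_than,,fat
14B,saturated_fat,5,g,greater_than,,saturated_fat
14B,sodium,450,mg,greater_than,,sodium
15,total_sugar,10,g,greater_than,,sugar
15,sodium,100,mg,greater_than,,sodium
16,total_fat,5,g,greater_than,,fat
16,total_sugar,10,g,greater_than,,sugar
16,sodium,350,mg,greater_than,,sodium
17,total_fat,10,g,greater_than,,fat
17,saturated_fat,4,g,greater_than,,saturated_fat
17,sodium,400,mg,greater_than,,sodium
18,total_fat,10,g,greater_than,,fat
18,saturated_fat,4,g,greater_than,,saturated_fat
18,total_sugar,10,g,greater_than,,sugar
18,sodium,750,mg,greater_than,,sodium
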