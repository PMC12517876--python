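rule_id,pattern,nova_group,priority
R4_SODA,SODA,4,20
R4_SOFT_DRINK,SOFT DRINK,4,20
R4_COLA,COLA,4,20
R4_ENERGY_DRINK,ENERGY DRINK,4,20
R4_SPORTS_DRINK,SPORTS DRINK,4,20
R4_FRUIT_DRINK,FRUIT DRINK,4,20
R4_CANDY,CANDY,4,20
R4_CHOCOLATE_BAR,CHOCOLATE BAR,4,20
R4_COOKIE,COOKIE,4,20
R4_COOKIES,COOKIES,4,20
R4_SNACK,SNACK,4,20
R4_DOUGHNUT,DOUGHNUT,4,20
R4_ICE_CREAM,ICE CREAM,4,20
R4_CHIPS,CHIPS,4,20
R4_CRACKER,CRACKER,4,20
R4_CRACKERS,CRACKERS,4,20
R4_PRETZELS,PRETZELS,4,20
R4_NUGGETS,NUGGETS,4,20
R4_HOT_DOG,HOT DOG,4,20
R4_FRANKFURTER,FRANKFURTER,4,20
R4_SAUSAGE,SAUSAGE,4,20
R4_LUNCHEON_MEAT,LUNCHEON MEAT,4,20
R4_BOLOGNA,BOLOGNA,4,20
R4_INSTANT_NOODLES,INSTANT NOODLES,4,20
R4_RAMEN,RAMEN,4,20
R4_FROZEN_MEAL,FROZEN MEAL,4,20
R4_FROZEN_DINNER,FROZEN DINNER,4,20
R4_READY_TO_HEAT,READY TO HEAT,4,20
R4_READY_TO_EAT,READY TO EAT,4,20
R4_PIZZA,PIZZA,4,20
R4_COMMERCIAL,COMMERCIALLY PREPARED,4,20
R4_MARGARINE,MARGARINE,4,20
R4_CHOCOLATE_MILK,CHOCOLATE MILK,4,20
R4_FLAVORED,FLAVORED,4,12
R4_SWEETENED,SWEETENED,4,12
R3_BRINE,BRINE,3,12
R3_SMOKED,SMOKED,3,12
R3_CURED,CURED,3,12
R3_ROASTED_SALTED,ROASTED SALTED,3,15
R3_FRESHLY_BAKED,FRESHLY BAKED,3,15
R3_CANNED,CANNED,3,10
R3_CHEESE,CHEESE,3,10
R3_PICKLES,PICKLES,3,10
R3_HAM,HAM,3,10
R3_BEER,BEER,3,10
R3_WINE,WINE,3,10
R3_BREAD,BREAD,3,6
R2_SUGAR,SUGAR,2,8
R2_OIL,OIL,2,8
R2_BUTTER,BUTTER,2,8
R2_SALT,SALT,2,8
R2_HONEY,HONEY,2,8
R2_LARD,LARD,2,8
R1_CHICKEN_BREAST,CHICKEN BREAST,1,15
R1_YOGURT_PLAIN,YOGURT PLAIN,1,15
R1_PLAIN,PLAIN,1,7
R1_RAW,RAW,1,5
R1_FRESH,FRESH,1,5
R1_APPLE,APPLE,1,5
R1_BANANA,BANANA,1,5
R1_ORANGE,ORANGE,1,5
R1_MILK,MILK,1,5
R1_OATMEAL,OATMEAL,1,5
R1_RICE,RICE,1,5
R1_EGG,EGG,1,5
R1_CHICKEN,CHICKEN,1,5
R1_SPINACH,SPINACH,1,5
R1_CARROTS,CARROTS,1,5
R1_BEANS,BEANS,1,5
R1_SALMON,SALMON,1,5
R1_FISH,FISH,1,5
R1_BEEF,BEEF,1,5
R1_PORK,PORK,1,5
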