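description,nova_group
APPLE RAW,1
BANANA RAW,1
ORANGE RAW ALL VARIETIES,1
MILK WHOLE PLAIN,1
MILK LOW FAT PLAIN,1
OATMEAL COOKED PLAIN,1
RICE WHITE COOKED PLAIN,1
RICE BROWN COOKED PLAIN,1
EGG WHOLE COOKED,1
CHICKEN BREAST ROASTED PLAIN,1
SPINACH FRESH COOKED,1
CARROTS RAW,1
BEANS BLACK COOKED PLAIN,1
SALMON FRESH BAKED,1
YOGURT PLAIN LOW FAT,1
SUGAR WHITE GRANULATED,2
OIL OLIVE,2
OIL VEGETABLE CORN,2
BUTTER STICK,2
SALT TABLE,2
HONEY,2
VEGETABLES CANNED IN BRINE,3
TUNA CANNED IN WATER,3
CHEESE CHEDDAR,3
BREAD FRESHLY BAKED WHEAT,3
PICKLES CUCUMBER DILL,3
NUTS ROASTED SALTED,3
SALMON SMOKED,3
BEER REGULAR,3
SOFT DRINK COLA,4
SODA ORANGE,4
ENERGY DRINK,4
FRUIT DRINK PUNCH,4
CANDY CHOCOLATE BAR,4
COOKIE CHOCOLATE CHIP COMMERCIAL,4
SNACK CAKE CREME FILLED,4
ICE CREAM REGULAR,4
POTATO CHIPS,4
CHICKEN NUGGETS FROZEN REHEATED,4
HOT DOG FRANKFURTER BEEF,4
INSTANT NOODLES RAMEN FLAVORED,4
FROZEN MEAL DINNER READY TO HEAT,4
BREAD WHITE COMMERCIALLY PREPARED,4
PIZZA PEPPERONI FROZEN,4
CEREAL READY TO EAT SWEETENED,4
CHOCOLATE MILK COMMERCIAL,4
MARGARINE TUB,4
LUNCHEON MEAT BOLOGNA,4
YOGURT FRUIT FLAVORED SWEETENED,4
GRAHAM CRACKERS,4
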