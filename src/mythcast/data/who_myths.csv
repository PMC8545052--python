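myth_id,keywords,mode,category,n_tweets,n_users
garlic,Garlic,AND,Prevent,8621,7109
alcohol,Alcohol,AND,Prevent,3301,3130
hot_baths,Hot baths,AND,Prevent,733,681
rinse_nose,Rinse nose,AND,Prevent,441,400
hot_peppers,Hot peppers,AND,Prevent,1458,1250
hand_dryers,Hand dryers,AND,Prevent,966,871
bleach_disinfectant,Bleach;Disinfectant,OR,Prevent,15926,13116
methanol_ethanol,Methanol;Ethanol,OR,Prevent,2286,2096
pneumonia_vaccines,Pneumonia vaccines,AND,Prevent,2340,1935
uv_lamps,Ultra-violet (UV) lamps,AND,Prevent,1611,1278
chlorine,Chlorine,AND,Prevent,474,445
thermal_scanners,Thermal scanners,AND,Detect,2710,2237
holding_breath,Holding your breath,AND,Detect,1224,1170
shoes,Shoes,AND,Spread,252,227
houseflies,Houseflies,AND,Spread,116,111
mosquitos,Mosquitos,AND,Spread,22176,20062
5g_mobile_networks,5G;5G Mobile networks,OR,Spread,33236,25931
cold_weather_snow,Cold weather;Snow,OR,Spread,701,672
hot_humid_climates,Hot and humid climates,AND,Spread,622,598
sunny_hot_weather,Sunny and hot weather,AND,Spread,3969,3704
older_younger_people,Older people;Younger people,OR,Spread,25126,22436
antibiotics,Antibiotics,AND,Treat,15068,13170
medicines,Medicines,AND,Treat,5445,4407
recovery,Recovery,AND,Misc,531,518
viruses_bacteria,Viruses;Bacteria,OR,Misc,66,64
masks_co2,Masks;CO2 intoxication,AND,Misc,371,326
masks_exercise,Masks;Exercise,AND,Misc,133,124
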