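dimension,subgroup,estimate,ci_lower,ci_upper,population
economic_status,Quintile 1 (poorest),34.03,30.44,37.82,1674
economic_status,Quintile 2,44.82,41.81,47.87,1869
economic_status,Quintile 3,63.99,60.98,66.89,1820
economic_status,Quintile 4,81.52,77.82,84.72,1707
economic_status,Quintile 5 (richest),88.18,85.23,90.61,1422
education,No education,37.92,34.94,41.00,2278
education,Primary school,59.57,56.59,62.49,3219
education,Secondary school +,81.34,79.00,83.47,2995
residence,Rural,39.41,36.37,42.53,3046
residence,Urban,73.76,71.34,76.04,5448
region,Cabinda,63.84,55.47,71.45,191
region,Zaire,79.64,74.09,84.26,186
region,Uige,38.06,30.22,46.58,460
region,Luanda,83.23,79.43,86.44,2696
region,Cuanza Norte,53.00,43.69,62.11,111
region,Cuanza Sul,31.52,24.64,39.31,676
region,Malanje,53.16,46.56,59.65,323
region,Lunda Norte,36.94,29.65,44.88,247
region,Benguela,58.05,51.92,63.94,754
region,Huambo,65.41,59.88,70.54,650
region,Bie,49.15,42.16,56.18,414
region,Moxico,36.65,29.80,44.08,167
region,Cuando Cubango,41.40,33.99,49.22,164
region,Namibe,67.77,58.95,75.48,108
region,Huila,48.24,41.68,54.87,763
region,Cunene,61.06,55.30,66.52,321
region,Lunda Sul,60.11,54.37,65.59,163
region,Bengo,64.78,54.64,73.73,92
national_average,National average,61.4464,,,8492
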