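age_group,2005_both,2005_male,2005_female,2025_both,2025_male,2025_female
30-34,30850.99,17592.98,13433.99,41757.25,23527.20,18411.35
35-39,68507.62,37086.87,31600.86,132672.61,66592.20,66057.05
40-44,95558.91,50673.19,45005.53,208583.40,100450.50,108037.26
45-49,108733.84,56657.05,52138.80,212397.08,103886.60,108507.95
50-54,113088.04,57927.77,55185.06,199796.52,104880.63,94980.95
55-59,87322.57,43504.07,43822.10,211773.70,112366.88,99428.81
60-64,77652.77,39262.72,38387.47,208798.32,104925.07,103868.01
65-69,84032.47,44516.68,39494.76,188886.63,92310.51,96575.24
70-74,79688.68,42916.44,36736.49,156602.38,75747.64,80858.27
75-79,55083.56,29088.84,25969.64,85485.92,41134.46,44355.27
80-84,32265.20,16661.19,15591.39,46607.62,23828.10,22764.25
85-89,11560.08,5832.10,5724.76,25284.12,12953.68,12320.66
90-94,2501.39,1282.16,1218.16,8707.87,4334.81,4371.24
95-99,463.80,233.62,230.04,1483.32,700.86,782.72
100+,0.00,0.00,0.00,0.00,0.00,0.00
Total,847309.93,443235.68,404539.03,1728836.74,867639.14,861319.02
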