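year,sex,age_group,condition,count,population,printed_proportion_pct
2016,men,60plus,mci,2099367,19388180,10.83
2025,men,60plus,mci,1951986,19780650,9.87
2034,men,60plus,mci,1712136,20501800,8.35
2043,men,60plus,mci,1512801,19896410,7.6
2016,men,60plus,dementia,1574037,19388180,8.12
2025,men,60plus,dementia,1701501,19780650,8.6
2034,men,60plus,dementia,1512435,20501800,7.38
2043,men,60plus,dementia,1176225,19896410,5.91
2016,men,60plus,frailty,1397898,19388180,7.21
2025,men,60plus,frailty,1610214,19780650,8.14
2034,men,60plus,frailty,1743082,20501800,8.5
2043,men,60plus,frailty,1721806,19896410,8.65
2016,men,60plus,dementia_and_frailty,419282,19388180,2.16
2025,men,60plus,dementia_and_frailty,494973,19780650,2.5
2034,men,60plus,dementia_and_frailty,483458,20501800,2.36
2043,men,60plus,dementia_and_frailty,402453,19896410,2.02
2016,women,60plus,mci,2510807,24105400,10.42
2025,women,60plus,mci,2719972,24762430,10.98
2034,women,60plus,mci,2714563,25492570,10.65
2043,women,60plus,mci,2353775,24599120,9.57
2016,women,60plus,dementia,3528476,24105400,14.64
2025,women,60plus,dementia,3328257,24762430,13.44
2034,women,60plus,dementia,3389978,25492570,13.3
2043,women,60plus,dementia,3469545,24599120,14.11
2016,women,60plus,frailty,2736493,24105400,11.35
2025,women,60plus,frailty,3159041,24762430,12.76
2034,women,60plus,frailty,3462453,25492570,13.58
2043,women,60plus,frailty,3514460,24599120,14.29
2016,women,60plus,dementia_and_frailty,1326273,24105400,5.5
2025,women,60plus,dementia_and_frailty,1385076,24762430,5.59
2034,women,60plus,dementia_and_frailty,1412591,25492570,5.54
2043,women,60plus,dementia_and_frailty,1508757,24599120,6.13
2016,men,60_74,mci,647838,12495730,5.18
2025,men,60_74,mci,379758,10983780,3.46
2034,men,60_74,mci,304765,11737240,2.6
2043,men,60_74,mci,323306,11556310,2.8
2016,men,60_74,dementia,241230,12495730,1.93
2025,men,60_74,dementia,120409,10983780,1.1
2034,men,60_74,dementia,73529,11737240,0.63
2043,men,60_74,dementia,80786,11556310,0.7
2016,men,60_74,frailty,253188,12495730,2.03
2025,men,60_74,frailty,209534,10983780,1.91
2034,men,60_74,frailty,201042,11737240,1.71
2043,men,60_74,frailty,223752,11556310,1.94
2016,men,60_74,dementia_and_frailty,22988,12495730,0.18
2025,men,60_74,dementia_and_frailty,12625,10983780,0.11
2034,men,60_74,dementia_and_frailty,7443,11737240,0.06
2043,men,60_74,dementia_and_frailty,8511,11556310,0.07
2016,women,60_74,mci,652112,13374790,4.88
2025,women,60_74,mci,575006,11580100,4.97
2034,women,60_74,mci,576853,12156230,4.75
2043,women,60_74,mci,588701,11999820,4.91
2016,women,60_74,dementia,540643,13374790,4.04
2025,women,60_74,dementia,401484,11580100,3.47
2034,women,60_74,dementia,357065,12156230,2.94
2043,women,60_74,dementia,370194,11999820,3.09
2016,women,60_74,frailty,256670,13374790,1.92
2025,women,60_74,frailty,225264,11580100,1.95
2034,women,60_74,frailty,202606,12156230,1.67
2043,women,60_74,frailty,219516,11999820,1.83
2016,women,60_74,dementia_and_frailty,56820,13374790,0.42
2025,women,60_74,dementia_and_frailty,37988,11580100,0.33
2034,women,60_74,dementia_and_frailty,29316,12156230,0.24
2043,women,60_74,dementia_and_frailty,31299,11999820,0.26
2016,men,75plus,mci,1452816,6892449,21.08
2025,men,75plus,mci,1571291,8797099,17.86
2034,men,75plus,mci,1404037,8764496,16.02
2043,men,75plus,mci,1190512,8340157,14.28
2016,men,75plus,dementia,1330830,6892449,19.31
2025,men,75plus,dementia,1579892,8797099,17.96
2034,men,75plus,dementia,1438631,8764496,16.41
2043,men,75plus,dementia,1094243,8340157,13.12
2016,men,75plus,frailty,1144626,6892449,16.61
2025,men,75plus,frailty,1400766,8797099,15.92
2034,men,75plus,frailty,1542012,8764496,17.59
2043,men,75plus,frailty,1498174,8340157,17.97
2016,men,75plus,dementia_and_frailty,396540,6892449,5.75
2025,men,75plus,dementia_and_frailty,482238,8797099,5.48
2034,men,75plus,dementia_and_frailty,476089,8764496,5.43
2043,men,75plus,dementia_and_frailty,393916,8340157,4.72
2016,women,75plus,mci,1862290,10730610,17.35
2025,women,75plus,mci,2146789,13182410,16.29
2034,women,75plus,mci,2136943,13336360,16.02
2043,women,75plus,mci,1763372,12599170,14.0
2016,women,75plus,dementia,2987831,10730610,27.84
2025,women,75plus,dementia,2926058,13182410,22.2
2034,women,75plus,dementia,3032892,13336360,22.74
2043,women,75plus,dementia,3099972,12599170,24.61
2016,women,75plus,frailty,2479944,10730610,23.11
2025,women,75plus,frailty,2933980,13182410,22.26
2034,women,75plus,frailty,3259602,13336360,24.44
2043,women,75plus,frailty,3294875,12599170,26.15
2016,women,75plus,dementia_and_frailty,1269639,10730610,11.83
2025,women,75plus,dementia_and_frailty,1346920,13182410,10.22
2034,women,75plus,dementia_and_frailty,1383218,13336360,10.37
2043,women,75plus,dementia_and_frailty,1477213,12599170,11.73
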