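period,group_type,group,invitees,screened,rate_printed
2015-2016,state,New South Wales,1034012,394942,38.2
2015-2016,state,Victoria,792634,331962,41.9
2015-2016,state,Queensland,623375,252307,40.5
2015-2016,state,South Australia,240393,113045,47.0
2015-2016,state,Western Australia,322950,138660,42.9
2015-2016,state,Tasmania,78778,36507,46.3
2015-2016,state,Northern Territory,20200,5996,29.7
2015-2016,state,Australian Capital Territory,48148,21023,43.7
2015-2016,disadvantage,Most advantaged,668974,284227,42.5
2015-2016,disadvantage,Q4,607641,251846,41.4
2015-2016,disadvantage,Q3,648775,265897,41.0
2015-2016,disadvantage,Q2,642776,265928,41.4
2015-2016,disadvantage,Most disadvantaged,591700,226269,38.2
2015-2016,remoteness,Major cities,2164677,863851,39.9
2015-2016,remoteness,Inner regional,650459,289105,44.4
2015-2016,remoteness,Outer regional,300786,125887,41.9
2015-2016,remoteness,Remote,44568,15599,35.0
2015-2016,total,Total,3160490,1294442,40.9
2017-2018,state,New South Wales,1645025,647242,39.3
2017-2018,state,Victoria,1261636,569868,45.2
2017-2018,state,Queensland,1011186,412972,40.8
2017-2018,state,South Australia,380599,180958,47.5
2017-2018,state,Western Australia,521537,228650,43.8
2017-2018,state,Tasmania,125073,59753,47.8
2017-2018,state,Northern Territory,37783,11104,29.4
2017-2018,state,Australian Capital Territory,76248,34231,44.9
2017-2018,disadvantage,Most advantaged,1062445,473117,44.5
2017-2018,disadvantage,Q4,972249,420694,43.3
2017-2018,disadvantage,Q3,1042838,442379,42.4
2017-2018,disadvantage,Q2,1026609,436707,42.5
2017-2018,disadvantage,Most disadvantaged,952663,370904,38.9
2017-2018,remoteness,Major cities,3449056,1436070,41.6
2017-2018,remoteness,Inner regional,1046458,476202,45.5
2017-2018,remoteness,Outer regional,486078,206031,42.4
2017-2018,remoteness,Remote,77495,26475,34.2
2017-2018,total,Total,5059087,2144778,42.4
2019-2020,state,New South Wales,1869033,778347,41.6
2019-2020,state,Victoria,1448103,673408,46.5
2019-2020,state,Queensland,1145808,471583,41.2
2019-2020,state,South Australia,432608,209543,48.4
2019-2020,state,Western Australia,586428,268775,45.8
2019-2020,state,Tasmania,141033,68019,48.2
2019-2020,state,Northern Territory,37869,10176,26.9
2019-2020,state,Australian Capital Territory,90938,42326,46.5
2019-2020,disadvantage,Most advantaged,1184880,556560,47.0
2019-2020,disadvantage,Q4,1125003,506511,45.0
2019-2020,disadvantage,Q3,1205588,527298,43.7
2019-2020,disadvantage,Q2,1162598,506318,43.6
2019-2020,disadvantage,Most disadvantaged,1070241,423995,39.6
2019-2020,remoteness,Major cities,3971707,1722590,43.4
2019-2020,remoteness,Inner regional,1172420,547146,46.7
2019-2020,remoteness,Outer regional,526069,225004,42.8
2019-2020,remoteness,Remote,81624,27437,33.6
2019-2020,total,Total,5751820,2522177,43.8
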