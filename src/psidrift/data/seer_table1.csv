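variable,sample,category,count
age_group,2000,15-19,260
age_group,2000,20-24,663
age_group,2000,25-29,1408
age_group,2000,30-34,2551
age_group,2000,35-39,4989
age_group,2000,40-44,8726
age_group,2000,45-49,13039
age_group,2000,50-54,18966
age_group,2000,55-59,23800
age_group,2000,60-64,27699
age_group,2000,65-69,32891
age_group,2000,70-74,35945
age_group,2000,75-79,33045
age_group,2000,80-84,22046
age_group,2000,85+,16704
age_group,2015,15-19,327
age_group,2015,20-24,818
age_group,2015,25-29,1830
age_group,2015,30-34,3154
age_group,2015,35-39,4913
age_group,2015,40-44,8212
age_group,2015,45-49,13487
age_group,2015,50-54,23075
age_group,2015,55-59,31918
age_group,2015,60-64,39638
age_group,2015,65-69,45892
age_group,2015,70-74,38254
age_group,2015,75-79,29299
age_group,2015,80-84,21711
age_group,2015,85+,21237
age_group,2016,15-19,338
age_group,2016,20-24,888
age_group,2016,25-29,1845
age_group,2016,30-34,3376
age_group,2016,35-39,5039
age_group,2016,40-44,7948
age_group,2016,45-49,13206
age_group,2016,50-54,22410
age_group,2016,55-59,32388
age_group,2016,60-64,40104
age_group,2016,65-69,47686
age_group,2016,70-74,39901
age_group,2016,75-79,30180
age_group,2016,80-84,21523
age_group,2016,85+,21508
age_group,2017,15-19,289
age_group,2017,20-24,816
age_group,2017,25-29,1840
age_group,2017,30-34,3258
age_group,2017,35-39,5131
age_group,2017,40-44,8060
age_group,2017,45-49,13574
age_group,2017,50-54,21845
age_group,2017,55-59,32540
age_group,2017,60-64,42007
age_group,2017,65-69,48664
age_group,2017,70-74,43173
age_group,2017,75-79,31373
age_group,2017,80-84,22087
age_group,2017,85+,21179
age_group,2018,15-19,307
age_group,2018,20-24,802
age_group,2018,25-29,1734
age_group,2018,30-34,3263
age_group,2018,35-39,5215
age_group,2018,40-44,8183
age_group,2018,45-49,13375
age_group,2018,50-54,21140
age_group,2018,55-59,31763
age_group,2018,60-64,42480
age_group,2018,65-69,48336
age_group,2018,70-74,44597
age_group,2018,75-79,33207
age_group,2018,80-84,22374
age_group,2018,85+,21297
age_group,2019,15-19,321
age_group,2019,20-24,812
age_group,2019,25-29,1754
age_group,2019,30-34,3391
age_group,2019,35-39,5377
age_group,2019,40-44,8564
age_group,2019,45-49,13562
age_group,2019,50-54,20996
age_group,2019,55-59,32569
age_group,2019,60-64,43695
age_group,2019,65-69,50314
age_group,2019,70-74,47002
age_group,2019,75-79,35108
age_group,2019,80-84,23029
age_group,2019,85+,21336
age_group,2020,15-19,310
age_group,2020,20-24,751
age_group,2020,25-29,1576
age_group,2020,30-34,3208
age_group,2020,35-39,5019
age_group,2020,40-44,7839
age_group,2020,45-49,12302
age_group,2020,50-54,18681
age_group,2020,55-59,28342
age_group,2020,60-64,38976
age_group,2020,65-69,45153
age_group,2020,70-74,42869
age_group,2020,75-79,32284
age_group,2020,80-84,20778
age_group,2020,85+,18841
sex,2000,Male,122045
sex,2000,Female,120687
sex,2015,Male,134104
sex,2015,Female,149661
sex,2016,Male,137671
sex,2016,Female,150669
sex,2017,Male,142201
sex,2017,Female,153635
sex,2018,Male,143046
sex,2018,Female,155027
sex,2019,Male,149010
sex,2019,Female,158820
sex,2020,Male,133557
sex,2020,Female,143372
cancer_group,2000,Breast,51078
cancer_group,2000,Colorectal,111303
cancer_group,2000,Genitourinary,200929
cancer_group,2000,Lung,45748
cancer_group,2000,Melanoma,12712
cancer_group,2015,Breast,64137
cancer_group,2015,Colorectal,108870
cancer_group,2015,Genitourinary,235916
cancer_group,2015,Lung,49469
cancer_group,2015,Melanoma,22842
cancer_group,2016,Breast,64335
cancer_group,2016,Colorectal,109632
cancer_group,2016,Genitourinary,244809
cancer_group,2016,Lung,49489
cancer_group,2016,Melanoma,22797
cancer_group,2017,Breast,66014
cancer_group,2017,Colorectal,108315
cancer_group,2017,Genitourinary,255629
cancer_group,2017,Lung,49893
cancer_group,2017,Melanoma,23374
cancer_group,2018,Breast,67371
cancer_group,2018,Colorectal,109503
cancer_group,2018,Genitourinary,258067
cancer_group,2018,Lung,49167
cancer_group,2018,Melanoma,23508
cancer_group,2019,Breast,69369
cancer_group,2019,Colorectal,111858
cancer_group,2019,Genitourinary,268403
cancer_group,2019,Lung,50099
cancer_group,2019,Melanoma,24564
cancer_group,2020,Breast,63066
cancer_group,2020,Colorectal,99771
cancer_group,2020,Genitourinary,245058
cancer_group,2020,Lung,44280
cancer_group,2020,Melanoma,20948
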