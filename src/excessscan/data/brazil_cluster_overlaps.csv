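cancer_type,n_models,location,models,n_cities,population_thousands,expected_cases,observed_cases,p_min,p_max,excess_percent
Total Cancer,4,H1,XGB|RF|SVM|LASSO,16,538.220,643,815,0.001,0.002,27
Total Cancer,3,F11,XGB|RF|LASSO,1,253.877,309,408,0.001,0.005,32
Total Cancer,2,D1,SVM|LASSO,1,475.691,447,623,0.001,0.001,40
Total Cancer,2,E3,SVM|LASSO,20,587.156,641,820,0.001,0.001,28
Total Cancer,1,C1,LASSO,18,500.042,334,445,0.001,0.001,33
Total Cancer,1,A4,LASSO,18,556.312,416,550,0.001,0.001,32
Total Cancer,1,H2,LASSO,16,574.415,635,806,0.001,0.001,27
Total Cancer,1,C3,LASSO,23,592.999,392,496,0.002,0.002,27
Total Cancer,1,C7,LASSO,32,539.167,356,442,0.046,0.046,24
Total Cancer,1,C6,LASSO,26,586.597,428,537,0.002,0.002,25
Total Cancer,1,A2,LASSO,22,474.579,425,544,0.001,0.001,28
Total Cancer,1,A5,LASSO,2,308.748,296,375,0.047,0.047,27
Total Cancer,1,D2,XGB,2,498.045,507,642,0.001,0.001,27
Total Cancer,1,A3,RF,12,446.095,236,315,0.04,0.04,33
Total Cancer,1,E2,RF,13,401.607,455,564,0.047,0.047,24
Total Cancer,1,"H (2, 3)",SVM,17,576.921,641,809,0.003,0.003,26
Colorectal C.,2,I5,SVM|LASSO,16,538.220,47,79,0.001,0.001,70
Esophagus C.,3,F2,XGB|RF|LASSO,28,571.144,41,61,0.002,0.007,50
Esophagus C.,3,E4,XGB|RF|LASSO,28,565.803,45,80,0.001,0.001,76
Esophagus C.,3,F6,XGB|RF|LASSO,5,586.686,26,47,0.001,0.003,78
Esophagus C.,2,F1,RF|SVM,10,573.875,31,47,0.033,0.035,52
Esophagus C.,2,"I (1, 2)",XGB|RF,16,584.172,44,65,0.001,0.004,48
Esophagus C.,1,E5,SVM,27,583.542,44,80,0.001,0.001,82
Esophagus C.,1,E1,SVM,15,431.730,32,48,0.033,0.033,50
Esophagus C.,1,F,XGB,2,443.871,21,37,0.013,0.013,76
Esophagus C.,1,F3,SVM,31,591.580,47,64,0.017,0.017,36
Esophagus C.,1,F4,LASSO,17,587.888,27,45,0.031,0.031,67
Esophagus C.,1,"I (1, 3)",LASSO,10,476.257,28,55,0.001,0.001,96
Esophagus C.,1,"F (5, 7)",SVM,9,551.007,29,46,0.015,0.015,59
Esophagus C.,1,F7,SVM,2,522.051,14,31,0.002,0.002,121
Esophagus C.,1,I1,SVM,6,323.479,21,39,0.004,0.004,86
Esophagus C.,1,F7,SVM,1,353.043,8,21,0.013,0.013,163
Lung C.,2,H2,SVM|LASSO,16,574.415,97,152,0.001,0.001,57
Lung C.,2,H4,SVM|LASSO,6,591.722,107,161,0.001,0.001,50
Lung C.,2,H5,SVM|LASSO,20,506.420,100,146,0.002,0.007,46
Lung C.,2,D2,SVM|LASSO,2,498.045,59,99,0.002,0.002,68
Lung C.,2,C2,SVM|LASSO,16,555.057,40,70,0.015,0.019,75
Lung C.,1,H6,LASSO,9,524.379,106,147,0.044,0.044,39
Lung C.,1,H7,LASSO,2,452.728,86,124,0.047,0.047,44
Non-Specified Location C.,4,F9,XGB|RF|SVM|LASSO,16,422.324,24,37,0.013,0.037,56
Non-Specified Location C.,4,A1,XGB|RF|SVM|LASSO,9,508.427,19,37,0.001,0.001,100
Non-Specified Location C.,4,I6,XGB|RF|SVM|LASSO,1,340.257,16,35,0.001,0.001,122
Non-Specified Location C.,4,I4,XGB|RF|SVM|LASSO,3,168.828,7,26,0.001,0.001,285
Non-Specified Location C.,4,E6,XGB|RF|SVM|LASSO,1,25.389,1,14,0.001,0.001,1300
Non-Specified Location C.,4,F10,XGB|RF|SVM|LASSO,1,108.145,4,15,0.001,0.003,275
Non-Specified Location C.,2,A6,SVM|LASSO,1,303.002,7,19,0.001,0.029,171
Non-Specified Location C.,2,E8,RF|SVM,1,159.076,7,17,0.023,0.04,162
Non-Specified Location C.,1,F8,RF,1,381.407,15,27,0.019,0.019,80
Non-Specified Location C.,1,A7,SVM,1,39.190,1,8,0.01,0.01,700
Non-Specified Location C.,1,E7,SVM,6,524.942,20,35,0.013,0.013,75
Stomach C.,3,B2,XGB|SVM|LASSO,5,597.394,51,92,0.001,0.022,82
Stomach C.,2,C4,SVM|LASSO,13,364.233,27,50,0.021,0.028,85
Stomach C.,2,D2,SVM|LASSO,2,498.045,33,58,0.017,0.023,76
Stomach C.,2,C5,SVM|LASSO,17,585.956,38,65,0.011,0.014,71
Stomach C.,2,B3,SVM|LASSO,2,594.948,46,80,0.001,0.002,74
Stomach C.,1,B1,RF,5,577.729,57,90,0.006,0.006,58
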