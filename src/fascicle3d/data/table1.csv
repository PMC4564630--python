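specimen_id,specimen_number,side,sex,age_years,category,rct_location,coronal_cm,sagittal_cm,posterior_region
1460R,1460,R,F,67,A,SP,,,yes
1463R,1463,R,F,95,A,SP,,,yes
1429R,1429,R,F,64,A,SP,,,yes
1425R,1425,R,M,89,A,SP,,,yes
1458R,1458,R,F,73,B,SP,1.88,1.63,yes
1450R,1450,R,F,77,B,SP,1.04,2.08,yes
1447R,1447,R,F,94,B,SP,1.47,1.52,yes
1447L,1447,L,F,94,B,SP,1.40,1.17,yes
1455R,1455,R,F,82,C,"SP,SSC,ISP",3.33,3.84,no
1427R,1427,R,M,76,C,"SP,SSC,ISP",5.0,3.00,no
1444R,1444,R,M,83,C,"SP,SSC,ISP",2.59,3.76,yes
1445L,1445,L,F,91,C,"SP,SSC,ISP",2.59,3.67,yes
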