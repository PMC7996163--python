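label,category,n,m,observed,predicted,residual,split
amchair 3.3,armchair,3,3,-20.00000,-18.93350,-1.06650,training
amchair 4.4,armchair,4,4,-19.70000,-18.83954,-0.86046,training
amchair 5.5,armchair,5,5,-18.80000,-18.77444,-0.02556,training
amchair 6.6,armchair,6,6,-18.50000,-18.72592,0.22592,validation
amchair 7.7,armchair,7,7,-18.20000,-18.68908,0.48908,training
amchair 8.8,armchair,8,8,-17.50000,-18.66083,1.16083,training
amchair 9.9,armchair,9,9,-17.20000,-18.63872,1.43872,training
chiral 3.2,chiral,3,2,-17.20000,-16.28865,-0.91135,validation
chiral 4.1,chiral,4,1,-17.20000,-15.58908,-1.61092,training
chiral 4.2,chiral,4,2,-17.00000,-15.84427,-1.15573,training
chiral 4.3,chiral,4,3,-16.30000,-15.96788,-0.33212,training
chiral 5.1,chiral,5,1,-16.20000,-15.56891,-0.63109,validation
chiral 5.2,chiral,5,2,-16.20000,-15.44925,-0.75075,training
chiral 5.3,chiral,5,3,-16.00000,-15.63349,-0.36651,training
chiral 5.4,chiral,5,4,-16.00000,-15.72809,-0.27191,training
chiral 6.1,chiral,6,1,-16.00000,-15.26864,-0.73136,validation
chiral 6.2,chiral,6,2,-15.90000,-15.19863,-0.70137,training
chiral 6.3,chiral,6,3,-15.90000,-15.37446,-0.52554,training
chiral 6.4,chiral,6,4,-15.90000,-15.47126,-0.42874,training
chiral 6.5,chiral,6,5,-15.80000,-15.39773,-0.40227,validation
chiral 7.1,chiral,7,1,-15.70000,-15.02346,-0.67654,training
chiral 7.2,chiral,7,2,-15.40000,-15.17288,-0.22712,training
chiral 7.3,chiral,7,3,-15.40000,-15.10112,-0.29888,training
chiral 7.4,chiral,7,4,-15.20000,-15.24345,0.04345,validation
chiral 7.5,chiral,7,5,-15.20000,-15.34078,0.14078,training
chiral 7.6,chiral,7,6,-15.20000,-15.28875,0.08875,training
chiral 8.1,chiral,8,1,-15.00000,-15.03210,0.03210,training
chiral 8.2,chiral,8,2,-15.00000,-14.77537,-0.22463,validation
chiral 8.3,chiral,8,3,-14.90000,-15.23422,0.33422,training
chiral 8.4,chiral,8,4,-14.80000,-15.08583,0.28583,training
chiral 8.5,chiral,8,5,-14.70000,-15.15833,0.45833,training
chiral 8.6,chiral,8,6,-14.70000,-15.24567,0.54567,validation
chiral 8.7,chiral,8,7,-14.70000,-15.20136,0.50136,training
chiral 9.3,chiral,9,3,-14.60000,-14.79209,0.19209,training
chiral 9.4,chiral,9,4,-14.50000,-15.12489,0.62489,training
chiral 9.5,chiral,9,5,-14.50000,-15.11612,0.61612,validation
chiral 9.6,chiral,9,6,-14.50000,-15.09848,0.59848,training
chiral 9.7,chiral,9,7,-14.30000,-15.29203,0.99203,training
zigzag 3.0,zigzag,3,0,-14.30000,-15.37860,1.07860,training
zigzag 4.0,zigzag,4,0,-14.10000,-14.00654,-0.09346,validation
zigzag 5.0,zigzag,5,0,-13.70000,-14.00654,0.30654,training
zigzag 6.0,zigzag,6,0,-13.70000,-13.79221,0.09221,training
zigzag 7.0,zigzag,7,0,-13.60000,-13.62087,0.02087,training
zigzag 8.0,zigzag,8,0,-13.30000,-13.48024,0.18024,validation
zigzag 9.0,zigzag,9,0,-12.90000,-13.36294,0.46294,training
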