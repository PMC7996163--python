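label,category,n,m,observed,predicted,residual,split
amchair 3.3,armchair,3,3,-34.80000,-33.04305,-1.75695,training
amchair 4.4,armchair,4,4,-33.10000,-31.92664,-1.17336,training
amchair 5.5,armchair,5,5,-32.30000,-31.36844,-0.93156,training
amchair 6.6,armchair,6,6,-32.30000,-30.81023,-1.48977,validation
amchair 7.7,armchair,7,7,-29.80000,-30.53113,0.73113,training
amchair 8.8,armchair,8,8,-29.10000,-30.25203,1.15203,training
amchair 9.9,armchair,9,9,-29.00000,-29.97293,0.97293,training
chiral 3.2,chiral,3,2,-28.50000,-26.92826,-1.57174,validation
chiral 4.1,chiral,4,1,-27.90000,-26.16358,-1.73642,training
chiral 4.2,chiral,4,2,-27.60000,-27.01059,-0.58941,training
chiral 4.3,chiral,4,3,-26.90000,-25.00316,-1.89684,training
chiral 5.1,chiral,5,1,-26.70000,-28.51704,1.81704,validation
chiral 5.2,chiral,5,2,-26.60000,-24.71436,-1.88564,training
chiral 5.3,chiral,5,3,-26.40000,-25.08549,-1.31451,training
chiral 5.4,chiral,5,4,-26.40000,-24.19447,-2.20553,training
chiral 6.1,chiral,6,1,-26.30000,-27.20385,0.90385,validation
chiral 6.2,chiral,6,2,-25.90000,-24.54620,-1.35380,training
chiral 6.3,chiral,6,3,-25.40000,-25.47553,0.07553,training
chiral 6.4,chiral,6,4,-25.00000,-24.13724,-0.86276,training
chiral 6.5,chiral,6,5,-24.80000,-24.44496,-0.35504,validation
chiral 7.1,chiral,7,1,-24.70000,-25.21534,0.51534,training
chiral 7.2,chiral,7,2,-24.60000,-26.28422,1.68422,training
chiral 7.3,chiral,7,3,-24.50000,-24.04522,-0.45478,training
chiral 7.4,chiral,7,4,-24.30000,-24.52728,0.22728,validation
chiral 7.5,chiral,7,5,-24.30000,-23.88676,-0.41324,training
chiral 7.6,chiral,7,6,-24.30000,-23.32855,-0.97145,training
chiral 8.1,chiral,8,1,-24.10000,-26.95336,2.85336,training
chiral 8.2,chiral,8,2,-24.10000,-23.51211,-0.58789,validation
chiral 8.3,chiral,8,3,-24.10000,-25.39320,1.29320,training
chiral 8.4,chiral,8,4,-24.00000,-24.63822,0.63822,training
chiral 8.5,chiral,8,5,-23.70000,-24.27680,0.57680,training
chiral 8.6,chiral,8,6,-23.50000,-22.90990,-0.59010,validation
chiral 8.7,chiral,8,7,-23.50000,-24.89841,1.39841,training
chiral 9.3,chiral,9,3,-23.00000,-23.42979,0.42979,training
chiral 9.4,chiral,9,4,-22.60000,-24.13724,1.53724,training
chiral 9.5,chiral,9,5,-22.50000,-23.71859,1.21859,validation
chiral 9.6,chiral,9,6,-22.40000,-23.16039,0.76039,training
chiral 9.7,chiral,9,7,-22.20000,-23.53151,1.33151,training
zigzag 3.0,zigzag,3,0,-22.10000,-25.42752,3.32752,training
zigzag 4.0,zigzag,4,0,-21.70000,-20.86901,-0.83099,validation
zigzag 5.0,zigzag,5,0,-21.50000,-20.86901,-0.63099,training
zigzag 6.0,zigzag,6,0,-21.40000,-20.17126,-1.22874,training
zigzag 7.0,zigzag,7,0,-21.10000,-19.61305,-1.48695,training
zigzag 8.0,zigzag,8,0,-20.90000,-19.19440,-1.70560,validation
zigzag 9.0,zigzag,9,0,-17.30000,-18.91530,1.61530,training
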