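# Synthetic residue-pair contact log-odds table (surrogate potential).
# Constructed from Kyte-Doolittle hydropathy as log_odds(a,b) = 0.02*h(a)*h(b):
# hydrophobic pairs score favorably (positive), mixed pairs unfavorably.
# This is NOT a trained statistical potential; it provides a symmetric,
# finite 20x20 propensity surface for the decoy/Z-score/AUL machinery.
# Residue order (rows and columns): A C D E F G H I K L M N P Q R S T V W Y
  0.0648   0.0900  -0.1260  -0.1260   0.1008  -0.0144  -0.1152   0.1620  -0.1404   0.1368   0.0684  -0.1260  -0.0576  -0.1260  -0.1620  -0.0288  -0.0252   0.1512  -0.0324  -0.0468
  0.0900   0.1250  -0.1750  -0.1750   0.1400  -0.0200  -0.1600   0.2250  -0.1950   0.1900   0.0950  -0.1750  -0.0800  -0.1750  -0.2250  -0.0400  -0.0350   0.2100  -0.0450  -0.0650
 -0.1260  -0.1750   0.2450   0.2450  -0.1960   0.0280   0.2240  -0.3150   0.2730  -0.2660  -0.1330   0.2450   0.1120   0.2450   0.3150   0.0560   0.0490  -0.2940   0.0630   0.0910
 -0.1260  -0.1750   0.2450   0.2450  -0.1960   0.0280   0.2240  -0.3150   0.2730  -0.2660  -0.1330   0.2450   0.1120   0.2450   0.3150   0.0560   0.0490  -0.2940   0.0630   0.0910
  0.1008   0.1400  -0.1960  -0.1960   0.1568  -0.0224  -0.1792   0.2520  -0.2184   0.2128   0.1064  -0.1960  -0.0896  -0.1960  -0.2520  -0.0448  -0.0392   0.2352  -0.0504  -0.0728
 -0.0144  -0.0200   0.0280   0.0280  -0.0224   0.0032   0.0256  -0.0360   0.0312  -0.0304  -0.0152   0.0280   0.0128   0.0280   0.0360   0.0064   0.0056  -0.0336   0.0072   0.0104
 -0.1152  -0.1600   0.2240   0.2240  -0.1792   0.0256   0.2048  -0.2880   0.2496  -0.2432  -0.1216   0.2240   0.1024   0.2240   0.2880   0.0512   0.0448  -0.2688   0.0576   0.0832
  0.1620   0.2250  -0.3150  -0.3150   0.2520  -0.0360  -0.2880   0.4050  -0.3510   0.3420   0.1710  -0.3150  -0.1440  -0.3150  -0.4050  -0.0720  -0.0630   0.3780  -0.0810  -0.1170
 -0.1404  -0.1950   0.2730   0.2730  -0.2184   0.0312   0.2496  -0.3510   0.3042  -0.2964  -0.1482   0.2730   0.1248   0.2730   0.3510   0.0624   0.0546  -0.3276   0.0702   0.1014
  0.1368   0.1900  -0.2660  -0.2660   0.2128  -0.0304  -0.2432   0.3420  -0.2964   0.2888   0.1444  -0.2660  -0.1216  -0.2660  -0.3420  -0.0608  -0.0532   0.3192  -0.0684  -0.0988
  0.0684   0.0950  -0.1330  -0.1330   0.1064  -0.0152  -0.1216   0.1710  -0.1482   0.1444   0.0722  -0.1330  -0.0608  -0.1330  -0.1710  -0.0304  -0.0266   0.1596  -0.0342  -0.0494
 -0.1260  -0.1750   0.2450   0.2450  -0.1960   0.0280   0.2240  -0.3150   0.2730  -0.2660  -0.1330   0.2450   0.1120   0.2450   0.3150   0.0560   0.0490  -0.2940   0.0630   0.0910
 -0.0576  -0.0800   0.1120   0.1120  -0.0896   0.0128   0.1024  -0.1440   0.1248  -0.1216  -0.0608   0.1120   0.0512   0.1120   0.1440   0.0256   0.0224  -0.1344   0.0288   0.0416
 -0.1260  -0.1750   0.2450   0.2450  -0.1960   0.0280   0.2240  -0.3150   0.2730  -0.2660  -0.1330   0.2450   0.1120   0.2450   0.3150   0.0560   0.0490  -0.2940   0.0630   0.0910
 -0.1620  -0.2250   0.3150   0.3150  -0.2520   0.0360   0.2880  -0.4050   0.3510  -0.3420  -0.1710   0.3150   0.1440   0.3150   0.4050   0.0720   0.0630  -0.3780   0.0810   0.1170
 -0.0288  -0.0400   0.0560   0.0560  -0.0448   0.0064   0.0512  -0.0720   0.0624  -0.0608  -0.0304   0.0560   0.0256   0.0560   0.0720   0.0128   0.0112  -0.0672   0.0144   0.0208
 -0.0252  -0.0350   0.0490   0.0490  -0.0392   0.0056   0.0448  -0.0630   0.0546  -0.0532  -0.0266   0.0490   0.0224   0.0490   0.0630   0.0112   0.0098  -0.0588   0.0126   0.0182
  0.1512   0.2100  -0.2940  -0.2940   0.2352  -0.0336  -0.2688   0.3780  -0.3276   0.3192   0.1596  -0.2940  -0.1344  -0.2940  -0.3780  -0.0672  -0.0588   0.3528  -0.0756  -0.1092
 -0.0324  -0.0450   0.0630   0.0630  -0.0504   0.0072   0.0576  -0.0810   0.0702  -0.0684  -0.0342   0.0630   0.0288   0.0630   0.0810   0.0144   0.0126  -0.0756   0.0162   0.0234
 -0.0468  -0.0650   0.0910   0.0910  -0.0728   0.0104   0.0832  -0.1170   0.1014  -0.0988  -0.0494   0.0910   0.0416   0.0910   0.1170   0.0208   0.0182  -0.1092   0.0234   0.0338
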