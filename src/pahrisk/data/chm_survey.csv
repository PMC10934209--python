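herb,part,Naph,Acy,Ace,Flu,Phe,Ant,Flt,Pyr,BaA,Chry,BbF,bkF,BaP,Ind(cd)P,DahA,BghiP,Naph_rsd,Acy_rsd,Ace_rsd,Flu_rsd,Phe_rsd,Ant_rsd,Flt_rsd,Pyr_rsd,BaA_rsd,Chry_rsd,BbF_rsd,bkF_rsd,BaP_rsd,Ind(cd)P_rsd,DahA_rsd,BghiP_rsd
glycyrrhizae,root_stem,42.313,13.600,31.851,24.576,153.753,154.849,97.790,99.612,31.207,50.084,148.469,nd,nd,nd,nd,nd,0.39,0.73,0.10,0.21,0.05,0.07,0.26,0.23,0.39,0.12,0.08,-,-,-,-,-
honeysuckle,flower,36.019,13.609,25.060,25.191,160.906,nd,52.555,42.752,nd,76.563,941.504,nd,39.928,nd,nd,nd,0.25,0.32,0.56,0.51,0.21,-,0.17,0.22,-,0.21,0.08,-,0.24,-,-,-
coix_lacryma,fruit_seed,21.666,22.913,24.754,nd,82.388,147.707,27.020,nd,nd,nd,nd,nd,nd,nd,nd,nd,0.36,0.37,0.50,-,0.58,0.29,0.83,-,-,-,-,-,-,-,-,-
ginseng,root_stem,60.153,nd,33.842,nd,103.442,121.351,18.462,18.190,nd,nd,nd,nd,nd,nd,nd,nd,0.59,-,0.47,-,0.22,0.29,0.76,0.83,-,-,-,-,-,-,-,-
lotus_seed,fruit_seed,37.674,18.681,27.726,nd,80.887,117.332,21.164,11.859,nd,nd,nd,22.594,nd,nd,nd,nd,0.40,0.55,0.52,-,0.30,0.23,0.64,0.21,-,-,-,0.48,-,-,-,-
sterculia_lychnophora,fruit_seed,40.844,27.400,38.175,12.241,168.640,112.253,41.773,52.345,nd,nd,462.085,nd,nd,nd,nd,nd,0.26,0.38,0.39,0.37,0.12,0.15,0.25,0.40,-,-,0.04,-,-,-,-,-
lycium_chinense,fruit_seed,48.876,11.378,39.044,18.880,47.045,nd,nd,11.683,nd,nd,nd,nd,nd,nd,nd,nd,0.31,0.32,0.12,0.40,0.18,-,-,0.19,-,-,-,-,-,-,-,-
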