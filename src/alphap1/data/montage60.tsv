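name	x	y	z
Fp1	-0.290060	0.951800	-0.099706
Fpz	-0.008831	0.998722	-0.049758
Fp2	0.273251	0.956720	-0.100103
AF7	-0.545679	0.826645	-0.137452
AF3	-0.344721	0.922043	0.176082
AFz	-0.007878	0.949673	0.313143
AF4	0.340999	0.922349	0.181639
AF8	0.532757	0.834831	-0.138664
F7	-0.762940	0.626487	-0.159488
F5	-0.707110	0.692065	0.145055
F3	-0.543123	0.732759	0.409978
F1	-0.294643	0.753921	0.587187
Fz	-0.007401	0.764029	0.645139
F2	0.294039	0.760649	0.578752
F4	0.537676	0.744854	0.395092
F6	0.705685	0.695364	0.135933
F8	0.755500	0.634686	-0.162459
FT7	-0.925239	0.341460	-0.165339
FC5	-0.887819	0.393875	0.237990
FC3	-0.686046	0.434689	0.583426
FC1	-0.372959	0.447198	0.812967
FCz	-0.006887	0.454464	0.890739
FC2	0.363512	0.457867	0.811306
FC4	0.682532	0.443383	0.581000
FC6	0.883314	0.405172	0.235781
FT8	0.918407	0.357996	-0.168427
T7	-0.988849	0.000614	-0.148919
C5	-0.953241	0.027102	0.300992
C3	-0.736185	0.049231	0.674987
C1	-0.395076	0.064666	0.916370
Cz	-0.006534	0.071176	0.997442
C2	0.395149	0.069539	0.915981
C4	0.738592	0.057798	0.671671
C6	0.953894	0.038138	0.297711
T8	0.988218	0.012361	-0.152554
TP7	-0.937930	-0.327155	-0.115135
CP5	-0.891246	-0.336915	0.303593
CP3	-0.681210	-0.326280	0.655358
CP1	-0.365028	-0.311819	0.877225
CPz	-0.006431	-0.309648	0.950829
CP2	0.374207	-0.310610	0.873779
CP4	0.687794	-0.320582	0.651280
CP6	0.895619	-0.326846	0.301725
TP8	0.937658	-0.327002	-0.117763
P9	-0.712825	-0.555424	-0.428234
P7	-0.786499	-0.614275	-0.063924
P5	-0.723562	-0.637888	0.263736
P3	-0.551407	-0.639913	0.535221
P1	-0.293475	-0.637849	0.712055
Pz	-0.006931	-0.634976	0.772501
P2	0.301894	-0.629648	0.715824
P4	0.554515	-0.634260	0.538728
P6	0.718610	-0.643148	0.264500
P8	0.782470	-0.619239	-0.065451
P10	0.704097	-0.563574	-0.432009
PO3	-0.380594	-0.859403	0.341431
POz	-0.008345	-0.877194	0.480064
PO4	0.365826	-0.867596	0.336822
O1	-0.300828	-0.952210	0.052904
O2	0.286786	-0.956532	0.052918
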