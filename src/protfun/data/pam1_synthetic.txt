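# Synthetic PAM1-style substitution probability matrix (column-stochastic).
# prob[i][j] = probability that amino acid j is replaced by amino acid i
# per unit-PAM mutation event. Diagonal = Dayhoff per-residue retention
# probabilities; off-diagonal mass allocated by background frequency.
          A         R         N         D         C         Q         E         G         H         I         L         K         M         F         P         S         T         W         Y         V
A  0.986700  0.000788  0.001611  0.001286  0.000243  0.001120  0.001235  0.000620  0.000792  0.001155  0.000503  0.000700  0.001112  0.000489  0.000678  0.001495  0.001190  0.000211  0.000493  0.000920
R  0.000597  0.991300  0.000759  0.000606  0.000114  0.000528  0.000582  0.000292  0.000373  0.000544  0.000237  0.000330  0.000524  0.000230  0.000319  0.000705  0.000561  0.000099  0.000232  0.000434
N  0.000582  0.000363  0.982200  0.000591  0.000112  0.000515  0.000568  0.000285  0.000364  0.000531  0.000231  0.000322  0.000511  0.000225  0.000312  0.000687  0.000547  0.000097  0.000227  0.000423
D  0.000684  0.000426  0.000871  0.985900  0.000131  0.000605  0.000667  0.000335  0.000428  0.000624  0.000272  0.000378  0.000601  0.000264  0.000366  0.000808  0.000643  0.000114  0.000266  0.000497
C  0.000480  0.000299  0.000611  0.000488  0.997300  0.000425  0.000468  0.000235  0.000300  0.000438  0.000191  0.000265  0.000422  0.000185  0.000257  0.000567  0.000451  0.000080  0.000187  0.000349
Q  0.000553  0.000344  0.000704  0.000562  0.000106  0.987600  0.000539  0.000271  0.000346  0.000505  0.000220  0.000306  0.000486  0.000214  0.000296  0.000653  0.000520  0.000092  0.000215  0.000402
E  0.000728  0.000453  0.000926  0.000739  0.000139  0.000644  0.986500  0.000356  0.000455  0.000664  0.000289  0.000402  0.000639  0.000281  0.000389  0.000859  0.000684  0.000121  0.000283  0.000529
G  0.001295  0.000807  0.001648  0.001315  0.000248  0.001146  0.001263  0.993500  0.000810  0.001182  0.000515  0.000716  0.001137  0.000500  0.000693  0.001530  0.001217  0.000216  0.000504  0.000941
H  0.000495  0.000308  0.000630  0.000503  0.000095  0.000438  0.000483  0.000242  0.991200  0.000451  0.000197  0.000273  0.000434  0.000191  0.000265  0.000584  0.000465  0.000082  0.000193  0.000360
I  0.000538  0.000335  0.000685  0.000547  0.000103  0.000476  0.000525  0.000264  0.000337  0.987200  0.000214  0.000298  0.000473  0.000208  0.000288  0.000636  0.000506  0.000090  0.000210  0.000391
L  0.001237  0.000770  0.001574  0.001256  0.000237  0.001094  0.001207  0.000606  0.000774  0.001129  0.994700  0.000684  0.001086  0.000478  0.000662  0.001461  0.001163  0.000206  0.000481  0.000899
K  0.001179  0.000734  0.001500  0.001197  0.000226  0.001043  0.001150  0.000577  0.000737  0.001076  0.000469  0.992600  0.001035  0.000455  0.000631  0.001392  0.001108  0.000196  0.000459  0.000857
M  0.000218  0.000136  0.000278  0.000222  0.000042  0.000193  0.000213  0.000107  0.000137  0.000199  0.000087  0.000121  0.987400  0.000084  0.000117  0.000258  0.000205  0.000036  0.000085  0.000159
F  0.000582  0.000363  0.000741  0.000591  0.000112  0.000515  0.000568  0.000285  0.000364  0.000531  0.000231  0.000322  0.000511  0.994600  0.000312  0.000687  0.000547  0.000097  0.000227  0.000423
P  0.000742  0.000462  0.000945  0.000754  0.000142  0.000657  0.000724  0.000363  0.000464  0.000677  0.000295  0.000410  0.000652  0.000287  0.992600  0.000876  0.000698  0.000124  0.000289  0.000539
S  0.001019  0.000634  0.001297  0.001035  0.000195  0.000901  0.000994  0.000499  0.000637  0.000929  0.000405  0.000563  0.000895  0.000393  0.000545  0.984000  0.000958  0.000170  0.000396  0.000740
T  0.000844  0.000526  0.001074  0.000857  0.000162  0.000747  0.000823  0.000413  0.000528  0.000770  0.000336  0.000467  0.000741  0.000326  0.000452  0.000997  0.987100  0.000140  0.000329  0.000613
W  0.000146  0.000091  0.000185  0.000148  0.000028  0.000129  0.000142  0.000071  0.000091  0.000133  0.000058  0.000080  0.000128  0.000056  0.000078  0.000172  0.000137  0.997600  0.000057  0.000106
Y  0.000437  0.000272  0.000556  0.000443  0.000084  0.000386  0.000426  0.000214  0.000273  0.000398  0.000174  0.000241  0.000383  0.000169  0.000234  0.000516  0.000410  0.000073  0.994500  0.000317
V  0.000946  0.000589  0.001204  0.000961  0.000181  0.000837  0.000923  0.000463  0.000592  0.000863  0.000376  0.000523  0.000831  0.000365  0.000506  0.001117  0.000889  0.000157  0.000368  0.990100
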