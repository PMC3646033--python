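# 30 quasi-uniform unit gradient directions (antipodally symmetric electrostatic repulsion)
 0.2390230665 -0.0775312532  0.9679136730
-0.2896026539  0.3265185046  0.8997310537
-0.0790046856 -0.6073120799  0.7905253299
 0.4187361436  0.6386067197  0.6456326351
-0.5716761729 -0.0616219039  0.8181620220
 0.7061825249 -0.2440580559  0.6646366728
-0.3917774429  0.7321503815  0.5571949876
-0.3767236010 -0.8552448243  0.3558589874
 0.8499701808  0.1451594440  0.5064379801
-0.9255919242  0.1479308025  0.3484193845
 0.4069005379 -0.8141193300  0.4142965952
 0.3656365016  0.9007847885  0.2343004771
-0.9050842230 -0.4103668475  0.1114522305
 0.9301338182 -0.3572304015  0.0850736187
-0.4431852475  0.8941531092  0.0638518111
-0.0236846305  0.9976782971  0.0638518111
-0.6571500601 -0.7489434411  0.0850736187
 0.9920862745  0.0578206219  0.1114522305
-0.7427303608  0.6272598326  0.2343004771
 0.0185692962 -0.9099524781  0.4142965952
 0.7505022350  0.5615606180  0.3484193845
-0.8199172645 -0.2669386665  0.5064379801
 0.7313579519 -0.5817902778  0.3558589874
 0.0061783759  0.8303587017  0.5571949876
-0.5115619972 -0.5445754458  0.6646366728
 0.5347101150  0.2114142819  0.8181620220
-0.6677603009  0.3704789887  0.6456326351
 0.3524743736 -0.5008308284  0.7905253299
 0.1044467583  0.4237627941  0.8997310537
-0.1755107700 -0.1798307293  0.9679136730
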