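group,replicate,value
cvA_w02,1,9.05
cvA_w02,2,9.74
cvA_w02,3,9.18
cvA_w02,4,7.12
cvA_w02,5,6.77
cvA_w07,1,40.32
cvA_w07,2,44.36
cvA_w07,3,42.52
cvA_w07,4,49.71
cvA_w07,5,43.77
cvA_w12,1,118.78
cvA_w12,2,100.76
cvA_w12,3,96.31
cvA_w12,4,131.45
cvA_w12,5,110.65
cvB_w02,1,11.02
cvB_w02,2,8.48
cvB_w02,3,9.49
cvB_w02,4,8.56
cvB_w02,5,9.11
cvB_w07,1,61.30
cvB_w07,2,46.05
cvB_w07,3,51.59
cvB_w07,4,56.09
cvB_w07,5,50.76
cvB_w12,1,135.83
cvB_w12,2,136.32
cvB_w12,3,147.20
cvB_w12,4,132.94
cvB_w12,5,144.65
cvC_w02,1,7.05
cvC_w02,2,7.37
cvC_w02,3,7.19
cvC_w02,4,8.54
cvC_w02,5,6.46
cvC_w07,1,20.79
cvC_w07,2,17.15
cvC_w07,3,16.05
cvC_w07,4,20.82
cvC_w07,5,17.08
cvC_w12,1,21.00
cvC_w12,2,18.62
cvC_w12,3,17.10
cvC_w12,4,23.74
cvC_w12,5,19.13
cvD_w02,1,6.59
cvD_w02,2,7.49
cvD_w02,3,5.92
cvD_w02,4,5.24
cvD_w02,5,6.29
cvD_w07,1,16.44
cvD_w07,2,14.54
cvD_w07,3,15.03
cvD_w07,4,17.61
cvD_w07,5,17.46
cvD_w12,1,20.69
cvD_w12,2,17.12
cvD_w12,3,18.88
cvD_w12,4,20.43
cvD_w12,5,18.52
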