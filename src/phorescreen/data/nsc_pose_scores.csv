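id,-PLP1,-PLP2,-PMF,-PMF04,Jain,LibDockScore,LigScore1,LigScore2,Ludi1,Ludi2,Ludi3
NSC35839,128.01,127.24,259.45,188.38,5.78,152.48,3.65,4.53,808,624,1333
NSC80116,131.87,134.17,270.73,193.51,5.78,154.91,2.63,3.75,782,623,1374
NSC143057,141.36,138.40,215.12,163.47,6.01,162.90,3.79,4.49,691,572,1069
NSC164472,114.29,125.19,202.62,142.87,4.11,129.24,4.20,5.67,761,633,996
NSC281260,134.57,139.96,207.72,149.91,8.11,169.53,0.68,-0.58,674,588,1138
NSC636831,128.45,125.65,231.45,166.82,5.73,161.51,0.75,0.13,693,592,984
NSC659829,139.17,142.52,207.47,158.28,2.75,143.76,4.30,3.91,826,640,734
NSC702105,115.87,114.15,222.21,142.65,4.30,142.34,2.38,2.43,690,549,808
NSC711731,131.92,132.18,189.08,130.37,8.01,151.50,1.32,-0.82,619,500,840
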