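sex,age,cum_risk_per100
male,0,0.00
male,5,0.00
male,10,0.00
male,15,0.00
male,20,0.00
male,25,0.01
male,30,0.02
male,35,0.05
male,40,0.10
male,45,0.24
male,50,0.50
male,55,1.00
male,60,1.90
male,65,3.30
male,70,5.00
male,75,7.00
male,80,8.70
male,85,10.00
female,0,0.00
female,5,0.00
female,10,0.00
female,15,0.00
female,20,0.00
female,25,0.005
female,30,0.01
female,35,0.025
female,40,0.05
female,45,0.12
female,50,0.25
female,55,0.50
female,60,0.95
female,65,1.65
female,70,2.50
female,75,3.50
female,80,4.35
female,85,5.00
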