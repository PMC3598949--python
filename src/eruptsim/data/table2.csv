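side,load,tooth,cap,basis,compression_pct
left,incisive,canine,coronal,volume,42.2
left,incisive,first_premolar,coronal,volume,69.3
left,incisive,second_premolar,coronal,volume,74.1
left,incisive,second_molar,coronal,volume,12.6
left,incisive,canine,apical,volume,24.2
left,incisive,first_premolar,apical,volume,44.6
left,incisive,second_premolar,apical,volume,32.0
left,incisive,second_molar,apical,volume,8.0
left,incisive,canine,coronal,bru,57.9
left,incisive,first_premolar,coronal,bru,79.1
left,incisive,second_premolar,coronal,bru,73.8
left,incisive,second_molar,coronal,bru,9.6
left,incisive,canine,apical,bru,22.4
left,incisive,first_premolar,apical,bru,45.2
left,incisive,second_premolar,apical,bru,25.0
left,incisive,second_molar,apical,bru,5.6
left,right_molar,canine,coronal,volume,38.4
left,right_molar,first_premolar,coronal,volume,78.5
left,right_molar,second_premolar,coronal,volume,75.4
left,right_molar,second_molar,coronal,volume,6.5
left,right_molar,canine,apical,volume,20.3
left,right_molar,first_premolar,apical,volume,50.2
left,right_molar,second_premolar,apical,volume,31.0
left,right_molar,second_molar,apical,volume,15.0
left,right_molar,canine,coronal,bru,51.0
left,right_molar,first_premolar,coronal,bru,89.0
left,right_molar,second_premolar,coronal,bru,67.8
left,right_molar,second_molar,coronal,bru,2.9
left,right_molar,canine,apical,bru,14.5
left,right_molar,first_premolar,apical,bru,46.7
left,right_molar,second_premolar,apical,bru,24.4
left,right_molar,second_molar,apical,bru,26.8
right,incisive,canine,coronal,volume,84.5
right,incisive,first_premolar,coronal,volume,56.1
right,incisive,second_premolar,coronal,volume,71.4
right,incisive,second_molar,coronal,volume,4.1
right,incisive,canine,apical,volume,16.4
right,incisive,first_premolar,apical,volume,61.0
right,incisive,second_premolar,apical,volume,43.5
right,incisive,second_molar,apical,volume,72.0
right,incisive,canine,coronal,bru,89.4
right,incisive,first_premolar,coronal,bru,74.7
right,incisive,second_premolar,coronal,bru,79.7
right,incisive,second_molar,coronal,bru,0.8
right,incisive,canine,apical,bru,16.8
right,incisive,first_premolar,apical,bru,51.7
right,incisive,second_premolar,apical,bru,54.0
right,incisive,second_molar,apical,bru,46.6
right,right_molar,canine,coronal,volume,56.0
right,right_molar,first_premolar,coronal,volume,37.9
right,right_molar,second_premolar,coronal,volume,62.1
right,right_molar,second_molar,coronal,volume,47.9
right,right_molar,canine,apical,volume,12.7
right,right_molar,first_premolar,apical,volume,52.8
right,right_molar,second_premolar,apical,volume,73.8
right,right_molar,second_molar,apical,volume,76.4
right,right_molar,canine,coronal,bru,64.5
right,right_molar,first_premolar,coronal,bru,39.8
right,right_molar,second_premolar,coronal,bru,67.3
right,right_molar,second_molar,coronal,bru,49.6
right,right_molar,canine,apical,bru,6.5
right,right_molar,first_premolar,apical,bru,52.4
right,right_molar,second_premolar,apical,bru,52.9
right,right_molar,second_molar,apical,bru,64.5
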