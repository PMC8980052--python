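pattern,category,priority
W0,falls,1
W1,falls,2
W22,struck,3
W50,struck,4
W51,struck,5
W52,struck,6
V2,MVC,7
V4,MVC,8
W21,sports,9
X9,assault,10
Y0,assault,11
Y3,other,12
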