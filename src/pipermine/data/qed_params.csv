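property,a,b,c,d,e,f,dmax,weight
MW,2.817065973,392.5754953,290.7489764,2.419764353,49.22325677,65.37051707,104.9805561,0.66
ALOGP,3.172690585,137.8624751,2.534937431,4.581497897,0.822739154,0.576295591,131.3186604,0.46
HBA,2.948620388,160.4605972,3.615294657,4.435986202,0.290141953,1.300669958,148.7763046,0.05
HBD,1.618662227,1010.051101,0.985094388,0.000000001,0.713820843,0.920922555,258.1632616,0.61
PSA,1.876861559,125.2232657,62.90773554,87.83366614,12.01999824,28.51324732,104.5686167,0.06
ROTB,0.01,272.4121427,2.55837997,1.565547684,1.271567166,2.758063707,105.4420403,0.65
AROM,3.21778897,957.7374108,2.274627939,0.000000001,1.317690384,0.375760881,312.337261,0.48
ALERTS,0.01,1199.094025,-0.09002883,0.000000001,0.185904477,0.875193782,417.725314,0.95
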