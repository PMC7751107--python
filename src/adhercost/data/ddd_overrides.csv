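atc_code,ddd_mg
C09AA02,20
C09AA04,8
C09AA05,10
C09AA06,20
C09AA10,4
C10AA01,40
C10AA02,40
C10AA03,40
C10AA05,10
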