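atc_code,ddd_mg
C09AA01,10
C09AA02,10
C09AA03,15
C09AA04,4
C09AA05,2.5
C09AA06,15
C09AA10,2
C09BA02,10
C09BA05,2.5
C07AB02,150
C07AB03,50
C07AB07,10
C07AG02,37.5
C10AA01,30
C10AA02,45
C10AA03,30
C10AA04,60
C10AA05,20
C10AA07,10
B01AC04,75
B01AC05,2
B01AC06,100
B01AC22,2.5
B01AC24,90
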