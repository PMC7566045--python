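location,level,metric,year,value_str
Global,global,u5mr,2019,37·1 (33·2 to 41·7)
Global,global,arc_u5mr_2010_19,2019,−4·0% (−5·1 to −2·9)
Global,global,q45_15_female,2019,0·10 (0·09 to 0·11)
Global,global,q45_15_male,2019,0·16 (0·15 to 0·17)
Global,global,e0_female,2019,76·1 (75·4 to 76·9)
Global,global,e0_male,2019,71·0 (70·1 to 71·9)
Global,global,e0_both,2019,73·5 (72·8 to 74·3)
Global,global,hale,2019,63·5 (60·8 to 66·1)
Global,global,deaths,2019,56 496·5 (53 714·0 to 59 172·5)
Global,global,under5_deaths,2019,5045·4 (4273·0 to 6017·7)
"Central Europe, eastern Europe, and central Asia",super-region,u5mr,2019,11·5 (10·4 to 12·8)
"Central Europe, eastern Europe, and central Asia",super-region,arc_u5mr_2010_19,2019,−3·8% (−4·8 to −2·8)
"Central Europe, eastern Europe, and central Asia",super-region,q45_15_female,2019,0·10 (0·09 to 0·11)
"Central Europe, eastern Europe, and central Asia",super-region,q45_15_male,2019,0·24 (0·22 to 0·26)
"Central Europe, eastern Europe, and central Asia",super-region,e0_female,2019,77·7 (76·8 to 78·6)
"Central Europe, eastern Europe, and central Asia",super-region,e0_male,2019,69·1 (67·9 to 70·3)
"Central Europe, eastern Europe, and central Asia",super-region,e0_both,2019,73·4 (72·5 to 74·3)
"Central Europe, eastern Europe, and central Asia",super-region,hale,2019,63·0 (60·2 to 65·3)
"Central Europe, eastern Europe, and central Asia",super-region,deaths,2019,4741·2 (4436·2 to 5047·8)
"Central Europe, eastern Europe, and central Asia",super-region,under5_deaths,2019,61·1 (52·2 to 72·1)
High income,super-region,u5mr,2019,4·9 (4·8 to 5·1)
High income,super-region,arc_u5mr_2010_19,2019,−2·1% (−2·5 to −1·7)
High income,super-region,q45_15_female,2019,0·06 (0·05 to 0·06)
High income,super-region,q45_15_male,2019,0·10 (0·10 to 0·10)
High income,super-region,e0_female,2019,83·8 (83·8 to 83·9)
High income,super-region,e0_male,2019,78·8 (78·7 to 78·9)
High income,super-region,e0_both,2019,81·3 (81·2 to 81·4)
High income,super-region,hale,2019,67·4 (64·2 to 70·4)
High income,super-region,deaths,2019,9951·5 (9886·3 to 10 019·8)
High income,super-region,under5_deaths,2019,55·6 (49·7 to 62·6)
Latin America and Caribbean,super-region,u5mr,2019,19·0 (16·2 to 22·3)
Latin America and Caribbean,super-region,arc_u5mr_2010_19,2019,−4·7% (−6·2 to −3·1)
Latin America and Caribbean,super-region,q45_15_female,2019,0·09 (0·08 to 0·10)
Latin America and Caribbean,super-region,q45_15_male,2019,0·17 (0·16 to 0·19)
Latin America and Caribbean,super-region,e0_female,2019,79·0 (78·0 to 80·0)
Latin America and Caribbean,super-region,e0_male,2019,72·9 (71·5 to 74·3)
Latin America and Caribbean,super-region,e0_both,2019,76·0 (74·8 to 77·1)
Latin America and Caribbean,super-region,hale,2019,64·7 (61·7 to 67·2)
Latin America and Caribbean,super-region,deaths,2019,3565·5 (3298·9 to 3863·5)
Latin America and Caribbean,super-region,under5_deaths,2019,186·9 (149·0 to 231·4)
North Africa and Middle East,super-region,u5mr,2019,24·4 (22·3 to 26·7)
North Africa and Middle East,super-region,arc_u5mr_2010_19,2019,−4·3% (−5·2 to −3·4)
North Africa and Middle East,super-region,q45_15_female,2019,0·10 (0·09 to 0·11)
North Africa and Middle East,super-region,q45_15_male,2019,0·15 (0·13 to 0·17)
North Africa and Middle East,super-region,e0_female,2019,75·5 (74·3 to 76·6)
North Africa and Middle East,super-region,e0_male,2019,72·3 (70·9 to 73·6)
North Africa and Middle East,super-region,e0_both,2019,73·8 (72·5 to 75·0)
North Africa and Middle East,super-region,hale,2019,63·3 (60·5 to 65·9)
North Africa and Middle East,super-region,deaths,2019,3099·5 (2812·9 to 3411·8)
North Africa and Middle East,super-region,under5_deaths,2019,300·0 (255·2 to 353·3)
South Asia,super-region,u5mr,2019,40·5 (36·0 to 46·0)
South Asia,super-region,arc_u5mr_2010_19,2019,−4·6% (−6·0 to −3·0)
South Asia,super-region,q45_15_female,2019,0·14 (0·12 to 0·16)
South Asia,super-region,q45_15_male,2019,0·19 (0·16 to 0·22)
South Asia,super-region,e0_female,2019,71·7 (70·1 to 73·4)
South Asia,super-region,e0_male,2019,69·1 (67·3 to 71·0)
South Asia,super-region,e0_both,2019,70·4 (69·2 to 71·7)
South Asia,super-region,hale,2019,60·7 (57·7 to 63·5)
South Asia,super-region,deaths,2019,11 939·1 (10 903·9 to 13 016·7)
South Asia,super-region,under5_deaths,2019,1357·5 (1143·5 to 1612·4)
"Southeast Asia, east Asia, and Oceania",super-region,u5mr,2019,14·8 (13·2 to 16·5)
"Southeast Asia, east Asia, and Oceania",super-region,arc_u5mr_2010_19,2019,−5·4% (−6·4 to −4·5)
"Southeast Asia, east Asia, and Oceania",super-region,q45_15_female,2019,0·07 (0·06 to 0·08)
"Southeast Asia, east Asia, and Oceania",super-region,q45_15_male,2019,0·14 (0·12 to 0·16)
"Southeast Asia, east Asia, and Oceania",super-region,e0_female,2019,79·2 (77·9 to 80·4)
"Southeast Asia, east Asia, and Oceania",super-region,e0_male,2019,73·2 (71·8 to 74·7)
"Southeast Asia, east Asia, and Oceania",super-region,e0_both,2019,76·1 (75·1 to 77·1)
"Southeast Asia, east Asia, and Oceania",super-region,hale,2019,65·8 (63·3 to 68·1)
"Southeast Asia, east Asia, and Oceania",super-region,deaths,2019,15 551·0 (14 134·9 to 16 985·4)
"Southeast Asia, east Asia, and Oceania",super-region,under5_deaths,2019,405·4 (349·0 to 467·0)
Sub-Saharan Africa,super-region,u5mr,2019,74·1 (65·3 to 85·2)
Sub-Saharan Africa,super-region,arc_u5mr_2010_19,2019,−4·0% (−5·3 to −2·8)
Sub-Saharan Africa,super-region,q45_15_female,2019,0·20 (0·18 to 0·23)
Sub-Saharan Africa,super-region,q45_15_male,2019,0·27 (0·25 to 0·30)
Sub-Saharan Africa,super-region,e0_female,2019,66·8 (65·1 to 68·1)
Sub-Saharan Africa,super-region,e0_male,2019,62·2 (60·4 to 63·7)
Sub-Saharan Africa,super-region,e0_both,2019,64·5 (62·8 to 65·9)
Sub-Saharan Africa,super-region,hale,2019,57·4 (54·8 to 59·8)
Sub-Saharan Africa,super-region,deaths,2019,7648·7 (6919·1 to 8577·3)
Sub-Saharan Africa,super-region,under5_deaths,2019,2678·8 (2219·8 to 3252·5)
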