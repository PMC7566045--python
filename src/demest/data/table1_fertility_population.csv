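location,level,metric,year,value_str
Global,global,population,2019,7 737 464·6 (7 482 639·9 to 7 992 501·5)
Global,global,population_15_64,2019,5 055 473·0 (4 879 934·2 to 5 232 218·8)
Global,global,population_under5,2019,662 842·7 (643 879·2 to 681 974·5)
Global,global,arc_population_2010_19,2019,1·1% (1·0 to 1·3)
Global,global,tfr,1950,4·97 (4·79 to 5·16)
Global,global,tfr,1980,3·82 (3·74 to 3·90)
Global,global,tfr,2019,2·31 (2·17 to 2·46)
Global,global,livebirths,1950,95 940·2 (92 550·3 to 99 388·8)
Global,global,livebirths,1980,130 420·3 (127 720·9 to 132 974·6)
Global,global,livebirths,2019,135 350·0 (127 167·1 to 144 081·2)
Global,global,nrr,2019,1·1 (1·0 to 1·1)
"Central Europe, eastern Europe, and central Asia",super-region,population,2019,417 725·1 (396 014·3 to 440 103·3)
"Central Europe, eastern Europe, and central Asia",super-region,population_15_64,2019,277 648·1 (263 234·8 to 292 468·6)
"Central Europe, eastern Europe, and central Asia",super-region,population_under5,2019,27 561·1 (25961·0 to 29 081·7)
"Central Europe, eastern Europe, and central Asia",super-region,arc_population_2010_19,2019,0·2% (−0·1 to 0·4)
"Central Europe, eastern Europe, and central Asia",super-region,tfr,1950,3·07 (3·00 to 3·15)
"Central Europe, eastern Europe, and central Asia",super-region,tfr,1980,2·26 (2·23 to 2·29)
"Central Europe, eastern Europe, and central Asia",super-region,tfr,2019,1·84 (1·66 to 2·06)
"Central Europe, eastern Europe, and central Asia",super-region,livebirths,1950,7593·5 (7417·7 to 7782·2)
"Central Europe, eastern Europe, and central Asia",super-region,livebirths,1980,7173·5 (7094·2 to 7257·0)
"Central Europe, eastern Europe, and central Asia",super-region,livebirths,2019,5206·6 (4672·8 to 5811·1)
"Central Europe, eastern Europe, and central Asia",super-region,nrr,2019,0·9 (0·8 to 1·0)
High income,super-region,population,2019,1 083 976·1 (1 036 700·3 to 1 131 810·4)
High income,super-region,population_15_64,2019,700 212·4 (669 195·0 to 731 848·0)
High income,super-region,population_under5,2019,56 941·9 (54 278·6 to 59 734·0)
High income,super-region,arc_population_2010_19,2019,0·5% (0·3 to 0·7)
High income,super-region,tfr,1950,2·84 (2·80 to 2·87)
High income,super-region,tfr,1980,1·87 (1·86 to 1·88)
High income,super-region,tfr,2019,1·63 (1·49 to 1·80)
High income,super-region,livebirths,1950,13 588·8 (13 426·7 to 13 752·3)
High income,super-region,livebirths,1980,12 482·3 (12 409·5 to 12 555·5)
High income,super-region,livebirths,2019,11 186·1 (10 206·9 to 12 315·2)
High income,super-region,nrr,2019,0·8 (0·7 to 0·9)
Latin America and Caribbean,super-region,population,2019,584 378·2 (550 808·2 to 616 150·2)
Latin America and Caribbean,super-region,population_15_64,2019,389 534·9 (366 772·0 to 410 991·0)
Latin America and Caribbean,super-region,population_under5,2019,48 074·1 (45 533·0 to 50 539·5)
Latin America and Caribbean,super-region,arc_population_2010_19,2019,1·1% (0·8 to 1·3)
Latin America and Caribbean,super-region,tfr,1950,6·05 (5·76 to 6·34)
Latin America and Caribbean,super-region,tfr,1980,4·27 (4·16 to 4·37)
Latin America and Caribbean,super-region,tfr,2019,2·07 (1·89 to 2·25)
Latin America and Caribbean,super-region,livebirths,1950,6504·1 (6209·5 to 6799·1)
Latin America and Caribbean,super-region,livebirths,1980,10 773·7 (10 520·3 to 11 028·0)
Latin America and Caribbean,super-region,livebirths,2019,9793·7 (8950·1 to 10 685·6)
Latin America and Caribbean,super-region,nrr,2019,1·0 (0·9 to 1·1)
North Africa and Middle East,super-region,population,2019,608 713·6 (585 677·9 to 634 586·8)
North Africa and Middle East,super-region,population_15_64,2019,400 862·6 (386 122·8 to 416 975·8)
North Africa and Middle East,super-region,population_under5,2019,59 719·9 (56 802·9 to 62 767·3)
North Africa and Middle East,super-region,arc_population_2010_19,2019,1·6% (1·5 to 1·8)
North Africa and Middle East,super-region,tfr,1950,6·88 (6·60 to 7·16)
North Africa and Middle East,super-region,tfr,1980,6·34 (6·19 to 6·48)
North Africa and Middle East,super-region,tfr,2019,2·50 (2·26 to 2·77)
North Africa and Middle East,super-region,livebirths,1950,5617·1 (5392·9 to 5838·0)
North Africa and Middle East,super-region,livebirths,1980,11 238·7 (10 969·5 to 11 490·4)
North Africa and Middle East,super-region,livebirths,2019,12 197·8 (11 052·0 to 13 533·2)
North Africa and Middle East,super-region,nrr,2019,1·2 (1·1 to 1·3)
South Asia,super-region,population,2019,1 805 200·3 (1 650 386·8 to 1 971 037·9)
South Asia,super-region,population_15_64,2019,1 174 895·9 (1 072 148·8 to 1 284 426·1)
South Asia,super-region,population_under5,2019,164 404·5 (151 118·0 to 178 694·1)
South Asia,super-region,arc_population_2010_19,2019,1·4% (1·1 to 1·8)
South Asia,super-region,tfr,1950,6·18 (5·70 to 6·66)
South Asia,super-region,tfr,1980,5·21 (4·97 to 5·44)
South Asia,super-region,tfr,2019,2·21 (2·03 to 2·40)
South Asia,super-region,livebirths,1950,20 216·6 (18 733·9 to 21 701·2)
South Asia,super-region,livebirths,1980,33 101·1 (31 750·4 to 34 432·9)
South Asia,super-region,livebirths,2019,33 438·5 (30 722·0 to 36 348·4)
South Asia,super-region,nrr,2019,1·0 (0·9 to 1·1)
"Southeast Asia, east Asia, and Oceania",super-region,population,2019,2 159 262·0 (1 973 725·4 to 2 334 066·8)
"Southeast Asia, east Asia, and Oceania",super-region,population_15_64,2019,1 521 841·5 (1 389 093·2 to 1 646 668·4)
"Southeast Asia, east Asia, and Oceania",super-region,population_under5,2019,140 474·2 (129 639·5 to 150 870·5)
"Southeast Asia, east Asia, and Oceania",super-region,arc_population_2010_19,2019,0·6% (0·1 to 1·0)
"Southeast Asia, east Asia, and Oceania",super-region,tfr,1950,6·04 (5·87 to 6·21)
"Southeast Asia, east Asia, and Oceania",super-region,tfr,1980,3·42 (3·36 to 3·47)
"Southeast Asia, east Asia, and Oceania",super-region,tfr,2019,1·67 (1·59 to 1·75)
"Southeast Asia, east Asia, and Oceania",super-region,livebirths,1950,33 486·0 (32 623·7 to 34 352·1)
"Southeast Asia, east Asia, and Oceania",super-region,livebirths,1980,37 910·4 (37 354·7 to 38 445·7)
"Southeast Asia, east Asia, and Oceania",super-region,livebirths,2019,26 800·3 (25 656·2 to 28 075·6)
"Southeast Asia, east Asia, and Oceania",super-region,nrr,2019,0·8 (0·7 to 0·8)
Sub-Saharan Africa,super-region,population,2019,1 078 209·3 (1 036 018·4 to 1 119 304·1)
Sub-Saharan Africa,super-region,population_15_64,2019,590 477·6 (567 469·7 to 612 781·8)
Sub-Saharan Africa,super-region,population_under5,2019,165 667·0 (159 058·5 to 171 945·1)
Sub-Saharan Africa,super-region,arc_population_2010_19,2019,2·6% (2·5 to 2·7)
Sub-Saharan Africa,super-region,tfr,1950,7·03 (6·67 to 7·38)
Sub-Saharan Africa,super-region,tfr,1980,6·79 (6·58 to 6·99)
Sub-Saharan Africa,super-region,tfr,2019,4·39 (4·12 to 4·71)
Sub-Saharan Africa,super-region,livebirths,1950,8934·2 (8474·2 to 9368·6)
Sub-Saharan Africa,super-region,livebirths,1980,17 740·7 (17 216·5 to 18 236·3)
Sub-Saharan Africa,super-region,livebirths,2019,36 726·9 (34 252·4 to 39 559·0)
Sub-Saharan Africa,super-region,nrr,2019,1·9 (1·8 to 2·1)
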