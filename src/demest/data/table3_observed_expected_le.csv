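location,level,metric,year,value_str
Global,global,observed_le,1990,67·2
Global,global,expected_le,1990,65·1
Global,global,difference_le,1990,2·1
Global,global,observed_le,2000,67·2
Global,global,expected_le,2000,67·2
Global,global,difference_le,2000,0·0
Global,global,observed_le,2010,70·6
Global,global,expected_le,2010,69·6
Global,global,difference_le,2010,1·0
Global,global,observed_le,2019,73·5
Global,global,expected_le,2019,71·7
Global,global,difference_le,2019,1·8
Low SDI,sdi-quintile,observed_le,1990,53·8
Low SDI,sdi-quintile,expected_le,1990,52·3
Low SDI,sdi-quintile,difference_le,1990,1·5
Low SDI,sdi-quintile,observed_le,2000,55·4
Low SDI,sdi-quintile,expected_le,2000,54·5
Low SDI,sdi-quintile,difference_le,2000,0·9
Low SDI,sdi-quintile,observed_le,2010,60·5
Low SDI,sdi-quintile,expected_le,2010,58·7
Low SDI,sdi-quintile,difference_le,2010,1·8
Low SDI,sdi-quintile,observed_le,2019,65·6
Low SDI,sdi-quintile,expected_le,2019,63·1
Low SDI,sdi-quintile,difference_le,2019,2·5
Low-middle SDI,sdi-quintile,observed_le,1990,59·7
Low-middle SDI,sdi-quintile,expected_le,1990,59·4
Low-middle SDI,sdi-quintile,difference_le,1990,0·3
Low-middle SDI,sdi-quintile,observed_le,2000,62·4
Low-middle SDI,sdi-quintile,expected_le,2000,63·4
Low-middle SDI,sdi-quintile,difference_le,2000,−1·0
Low-middle SDI,sdi-quintile,observed_le,2010,66·5
Low-middle SDI,sdi-quintile,expected_le,2010,67·1
Low-middle SDI,sdi-quintile,difference_le,2010,−0·6
Low-middle SDI,sdi-quintile,observed_le,2019,69·7
Low-middle SDI,sdi-quintile,expected_le,2019,69·7
Low-middle SDI,sdi-quintile,difference_le,2019,0·0
Middle SDI,sdi-quintile,observed_le,1990,67·0
Middle SDI,sdi-quintile,expected_le,1990,66·7
Middle SDI,sdi-quintile,difference_le,1990,0·3
Middle SDI,sdi-quintile,observed_le,2000,69·5
Middle SDI,sdi-quintile,expected_le,2000,69·4
Middle SDI,sdi-quintile,difference_le,2000,0·1
Middle SDI,sdi-quintile,observed_le,2010,72·1
Middle SDI,sdi-quintile,expected_le,2010,71·2
Middle SDI,sdi-quintile,difference_le,2010,0·9
Middle SDI,sdi-quintile,observed_le,2019,74·7
Middle SDI,sdi-quintile,expected_le,2019,72·6
Middle SDI,sdi-quintile,difference_le,2019,2·1
High-middle SDI,sdi-quintile,observed_le,1990,70·4
High-middle SDI,sdi-quintile,expected_le,1990,70·4
High-middle SDI,sdi-quintile,difference_le,1990,0·0
High-middle SDI,sdi-quintile,observed_le,2000,71·6
High-middle SDI,sdi-quintile,expected_le,2000,72·1
High-middle SDI,sdi-quintile,difference_le,2000,−0·5
High-middle SDI,sdi-quintile,observed_le,2010,75·0
High-middle SDI,sdi-quintile,expected_le,2010,73·9
High-middle SDI,sdi-quintile,difference_le,2010,1·1
High-middle SDI,sdi-quintile,observed_le,2019,77·5
High-middle SDI,sdi-quintile,expected_le,2019,75·2
High-middle SDI,sdi-quintile,difference_le,2019,2·3
High SDI,sdi-quintile,observed_le,1990,76·0
High SDI,sdi-quintile,expected_le,1990,75·9
High SDI,sdi-quintile,difference_le,1990,0·1
High SDI,sdi-quintile,observed_le,2000,78·1
High SDI,sdi-quintile,expected_le,2000,77·6
High SDI,sdi-quintile,difference_le,2000,0·5
High SDI,sdi-quintile,observed_le,2010,80·4
High SDI,sdi-quintile,expected_le,2010,79·0
High SDI,sdi-quintile,difference_le,2010,1·4
High SDI,sdi-quintile,observed_le,2019,81·2
High SDI,sdi-quintile,expected_le,2019,80·2
High SDI,sdi-quintile,difference_le,2019,1·0
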