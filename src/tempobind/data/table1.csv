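code,gender,age_months,education_years,raven_iq,decode_time_s,comprehension_time_s
DY01,1,84.53,2,92,358,302
DY02,1,84.59,2,82,432,420
DY03,1,87.49,3,81,332,292
DY04,1,98.69,3,97,378,345
DY05,1,101.66,3,88,312,301
DY06,1,106.49,4,82,310,258
DY07,1,108.56,3,75,373,331
DY08,1,114.66,5,74,280,215
DY09,1,123.39,5,92,244,217
DY10,1,149.39,7,79,202,175
DY11,1,150.36,7,84,182,163
DY12,2,85.43,2,79,330,295
DY13,2,95.10,4,94,292,234
DY14,2,97.92,2,73,362,311
DY15,2,101.69,3,77,325,253
DY16,2,110.69,4,74,298,298
DY17,2,112.33,5,86,250,205
DY18,2,120.66,5,67,275,242
DY19,2,126.62,6,86,192,157
DY20,2,132.49,6,72,195,180
DY21,2,133.46,6,95,228,152
DY22,2,136.62,6,83,235,182
DY23,2,143.43,7,64,213,177
DY24,2,145.95,7,71,214,165
DY25,2,147.33,7,72,257,212
DY26,2,153.16,7,80,201,175
DY27,2,105.46,9,100,NA,NA
DY28,2,159.66,5,100,NA,NA
DY29,1,123.13,9,96,NA,NA
DY30,1,158.76,8,100,NA,NA
DY31,1,150.26,8,NA,NA,NA
DY32,1,157.66,7,93,NA,NA
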