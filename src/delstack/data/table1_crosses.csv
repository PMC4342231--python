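gene,parent_labels,index,n_screened,A,B,D,AB,AD,BD,ABD
TaPFT1,tapft1-616-a x tapft1-157-b,1,316,55,51,,0,,,
TaPFT1,tapft1-616-a x tapft1-723-d,2,164,21,,18,,0,,
TaPFT1,tapft1-85-a x tapft1-734-d,2,85,14,,19,,9,,
TaPFT1,tapft1-157-b x tapft1-723-d,3,124,,17,17,,,0,
TaPFT1,tapft1-85-a x tapft1-157-b,1,124,22,19,,0,,,
TaPFT1,tapft1-616-a x tapft1-757-d,2,83,18,,4,,0,,
TaPFT1,tapft1-616-a x tapft1-734-d,2,39,5,,2,,2,,
TaPFT1,tapft1-157-b x tapft1-757-d,3,192,,41,23,,,3,
TaPFT1,tapft1-157-b x tapft1-734-d,3,110,,15,9,,,7,
TaPLDB1,tapldb1-690-a x tapldb1-150-b,1,75,8,16,,0,,,
TaPLDB1,tapldb1-781-a x tapldb1-855-b,1,48,3,10,,4,,,
TaPLDB1,tapldb1-334-a x tapldb1-855-b,1,40,4,2,,1,,,
TaPLDB1,tapldb1-208-a x tapldb1-855-b,1,48,8,12,,0,,,
TaPLDB1,tapldb1-781-a x tapldb1-934-d,2,134,31,,18,,9,,
TaPLDB1,tapldb1-334-a x tapldb1-147-d,2,94,24,,17,,5,,
TaPLDB1,tapldb1-781-a x tapldb1-147-d,2,42,4,,9,,5,,
TaPLDB1,tapldb1-855-b x tapldb1-147-d,3,92,,21,12,,,7,
TaPLDB1,tapldb1-150-b x tapldb1-934-d,3,32,,4,6,,,2,
TaWRKY11,tawrky11-208-a x tawrky11-743-b,1,104,16,22,,3,,,
TaWRKY11,tawrky11-286-a x tawrky11-87-b,1,51,11,10,,2,,,
TaWRKY11,tawrky11-227-a x tawrky11-87-b,1,76,4,11,,0,,,
TaWRKY11,tawrky11-417-a x tawrky11-87-b,1,44,4,6,,3,,,
TaWRKY11,tawrky11-227-a x tawrky11-300-d,2,48,4,,4,,1,,
TaWRKY11,tawrky11-417-a x tawrky11-300-d,2,48,8,,8,,6,,
TaWRKY11,tawrky11-286-a x tawrky11-300-d,2,48,5,,6,,4,,
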