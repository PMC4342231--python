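gene,parent_labels,index,n_screened,A,B,D,AB,AD,BD,ABD
TaPLDB1,tapldb1-781-a/855-b AD-tetra x tapldb1-934-d/147-d BD-tetra,4,79,,,,,13,19,5
TaPLDB1,tapldb1-334-a/855-b AD-tetra x tapldb1-147-d BD-tetra,4,64,,,,,9,9,4
TaWRKY11,tawrky11-417-a/87-b AB-tetra x tawrky11-300-d,5,252,,,,8,9,0,0
TaWRKY11,tawrky11-286-a/87-b AB-tetra x tawrky11-300-d,5,283,,,,7,2,0,0
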