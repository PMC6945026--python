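strain,published_wgs,chef_rep1,chef_rep2,chef_rep3,rr_10ng_rep1,gcc_10ng_rep1,rr_10ng_rep2,gcc_10ng_rep2,rr_10ng_rep3,gcc_10ng_rep3,rr_50ng_rep1,gcc_50ng_rep1,rr_50ng_rep2,gcc_50ng_rep2,rr_50ng_rep3,gcc_50ng_rep3,chef_doublet
MY16,68,56,76,71,65,64,60,64,78,79,110,87,110,89,91,81,True
JU775,70,63,81,66,100,93,78,79,93,96,139,112,138,110,110,102,False
ED3042,105,104,111,106,88,106,76,90,119,129,206,155,202,151,167,141,False
ED3040,149,146,156,160,121,154,127,138,182,187,281,224,279,216,234,204,False
MY6,193,201,217,229,191,194,161,173,243,248,356,285,351,283,302,265,False
MY14,237,236,253,267,266,259,202,202,263,273,419,319,415,319,341,291,False
PX174,298,,306,340,260,252,154,186,309,304,429,343,425,335,355,316,False
MY1,418,410,396,431,370,359,303,323,414,427,603,489,585,475,493,449,False
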