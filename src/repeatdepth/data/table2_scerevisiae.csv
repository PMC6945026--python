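strain,sra_accession,published_wgs_gcc,chef_rep1,chef_rep2,chef_rep3,reseq_gcc,ddpcr_rep1,ddpcr_rep2,ddpcr_rep3,role
BY4741,,,165,160,163,141,126,135,129,control
B30,,,,,,30,25,26,25,control
AHR,ERR1308770,31,166,174,171,157,,,,wild
AFG,ERR1309145,50,124,129,127,111,113,107,107,wild
ACQ,ERR1308618,74,114,,,96,,,,wild
AHG,ERR1308781,69,91,,,93,75,78,81,wild
AEF,ERR1308873,79,177,,,146,,,,wild
ACV,ERR1308596,92,96,,,,,,,wild
AHQ,ERR1309019,93,145,151,149,105,90,98,87,wild
CEB,ERR1309017,109,133,,,82,,,,wild
ACK,ERR1308893,116,124,,,97,,,,wild
ADA,ERR1309427,121,133,,,116,,,,wild
AAA,ERR1309487,136,171,169,171,139,135,133,137,wild
ABS,ERR1309033,201,210,226,221,179,195,192,180,wild
AEQ,ERR1309512,218,254,287,265,218,,,,wild
CEV,ERR1308745,243,306,306,300,255,238,216,228,wild
AES,ERR1309368,259,226,,,,,,,wild
AGC,ERR1309000,275,145,,,114,,,,wild
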