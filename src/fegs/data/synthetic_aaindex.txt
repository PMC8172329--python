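H SYN000101
D Synthetic fixture scale 1: values 1..20 in header order (synthetic, not from any database)
R PMID:0000000
A Synthetic, F.
T Synthetic fixture record
J None (2026)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.0     2.0     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0
    11.0    12.0    13.0    14.0    15.0    16.0    17.0    18.0    19.0    20.0
//
H SYN000201
D Synthetic fixture scale 2: reversed values (synthetic)
R PMID:0000000
A Synthetic, F.
T Synthetic fixture record
J None (2026)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    20.0    19.0    18.0    17.0    16.0    15.0    14.0    13.0    12.0    11.0
    10.0     9.0     8.0     7.0     6.0     5.0     4.0     3.0     2.0     1.0
//
H SYN000301
D Synthetic fixture scale 3: hydrophobicity-like mixed ordering (synthetic)
R PMID:0000000
A Synthetic, F.
T Synthetic fixture record
J None (2026)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.62   -2.53   -0.78   -0.90    0.29   -0.85   -0.74    0.48   -0.40    1.38
    1.06   -1.50    0.64    1.19    0.12   -0.18   -0.05    0.81    0.26    1.08
//
H SYN000401
D Synthetic fixture scale 4: many ties to exercise deterministic tie-breaking (synthetic)
R PMID:0000000
A Synthetic, F.
T Synthetic fixture record
J None (2026)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.0     1.0     2.0     2.0     3.0     3.0     4.0     4.0     5.0     5.0
     1.0     1.0     2.0     2.0     3.0     3.0     4.0     4.0     5.0     5.0
//
H SYN000501
D Synthetic fixture scale 5: volume-like magnitudes (synthetic)
R PMID:0000000
A Synthetic, F.
T Synthetic fixture record
J None (2026)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    88.6   173.4   114.1   111.1   108.5   143.8   138.4    60.1   153.2   166.7
   166.7   168.6   162.9   189.9   112.7    89.0   116.1   227.8   193.6   140.0
//
H SYN000601
D Synthetic fixture scale 6: exact duplicate of scale 2 (synthetic; must be dropped by deduplication)
R PMID:0000000
A Synthetic, F.
T Synthetic fixture record
J None (2026)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    20.0    19.0    18.0    17.0    16.0    15.0    14.0    13.0    12.0    11.0
    10.0     9.0     8.0     7.0     6.0     5.0     4.0     3.0     2.0     1.0
//
H SYN000701
D Synthetic fixture scale 7: record with missing values (synthetic; must be skipped)
R PMID:0000000
A Synthetic, F.
T Synthetic fixture record
J None (2026)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.0      NA     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0
    11.0    12.0      NA    14.0    15.0    16.0    17.0    18.0    19.0    20.0
//
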