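# SYNTHETIC pathway memberships: pathway sizes mirror the bundled
# enrichment summary; compound identifiers are placeholders.
pathway,compound_id
Glycerophospholipid metabolism,cpd0000
Glycerophospholipid metabolism,cpd0001
Glycerophospholipid metabolism,cpd0002
Glycerophospholipid metabolism,cpd0003
Glycerophospholipid metabolism,cpd0004
Glycerophospholipid metabolism,cpd0005
Glycerophospholipid metabolism,cpd0006
Glycerophospholipid metabolism,cpd0007
Glycerophospholipid metabolism,cpd0008
Glycerophospholipid metabolism,cpd0009
Glycerophospholipid metabolism,cpd0010
Glycerophospholipid metabolism,cpd0011
Glycerophospholipid metabolism,cpd0012
Glycerophospholipid metabolism,cpd0013
Glycerophospholipid metabolism,cpd0014
Glycerophospholipid metabolism,cpd0015
Glycerophospholipid metabolism,cpd0016
Glycerophospholipid metabolism,cpd0017
Glycerophospholipid metabolism,cpd0018
Glycerophospholipid metabolism,cpd0019
Glycerophospholipid metabolism,cpd0020
Glycerophospholipid metabolism,cpd0021
Glycerophospholipid metabolism,cpd0022
Glycerophospholipid metabolism,cpd0023
Glycerophospholipid metabolism,cpd0024
Glycerophospholipid metabolism,cpd0025
Glycerophospholipid metabolism,cpd0026
Glycerophospholipid metabolism,cpd0027
Glycerophospholipid metabolism,cpd0028
Glycerophospholipid metabolism,cpd0029
Glycerophospholipid metabolism,cpd0030
Glycerophospholipid metabolism,cpd0031
Glycerophospholipid metabolism,cpd0032
Glycerophospholipid metabolism,cpd0033
Glycerophospholipid metabolism,cpd0034
Glycerophospholipid metabolism,cpd0035
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0036
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0037
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0038
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0039
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0040
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0041
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0042
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0043
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0044
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0045
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0046
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0047
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0048
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,cpd0049
Sphingolipid metabolism,cpd0050
Sphingolipid metabolism,cpd0051
Sphingolipid metabolism,cpd0052
Sphingolipid metabolism,cpd0053
Sphingolipid metabolism,cpd0054
Sphingolipid metabolism,cpd0055
Sphingolipid metabolism,cpd0056
Sphingolipid metabolism,cpd0057
Sphingolipid metabolism,cpd0058
Sphingolipid metabolism,cpd0059
Sphingolipid metabolism,cpd0060
Sphingolipid metabolism,cpd0061
Sphingolipid metabolism,cpd0062
Sphingolipid metabolism,cpd0063
Sphingolipid metabolism,cpd0064
Sphingolipid metabolism,cpd0065
Sphingolipid metabolism,cpd0066
Sphingolipid metabolism,cpd0067
Sphingolipid metabolism,cpd0068
Sphingolipid metabolism,cpd0069
Sphingolipid metabolism,cpd0070
Linoleic acid metabolism,cpd0071
Linoleic acid metabolism,cpd0072
Linoleic acid metabolism,cpd0073
Linoleic acid metabolism,cpd0074
Linoleic acid metabolism,cpd0075
Alpha-linolenic acid metabolism,cpd0076
Alpha-linolenic acid metabolism,cpd0077
Alpha-linolenic acid metabolism,cpd0078
Alpha-linolenic acid metabolism,cpd0079
Alpha-linolenic acid metabolism,cpd0080
Alpha-linolenic acid metabolism,cpd0081
Alpha-linolenic acid metabolism,cpd0082
Alpha-linolenic acid metabolism,cpd0083
Alpha-linolenic acid metabolism,cpd0084
Alpha-linolenic acid metabolism,cpd0085
Alpha-linolenic acid metabolism,cpd0086
Alpha-linolenic acid metabolism,cpd0087
Alpha-linolenic acid metabolism,cpd0088
Phosphatidylinositol signaling system,cpd0089
Phosphatidylinositol signaling system,cpd0090
Phosphatidylinositol signaling system,cpd0091
Phosphatidylinositol signaling system,cpd0092
Phosphatidylinositol signaling system,cpd0093
Phosphatidylinositol signaling system,cpd0094
Phosphatidylinositol signaling system,cpd0095
Phosphatidylinositol signaling system,cpd0096
Phosphatidylinositol signaling system,cpd0097
Phosphatidylinositol signaling system,cpd0098
Phosphatidylinositol signaling system,cpd0099
Phosphatidylinositol signaling system,cpd0100
Phosphatidylinositol signaling system,cpd0101
Phosphatidylinositol signaling system,cpd0102
Phosphatidylinositol signaling system,cpd0103
Phosphatidylinositol signaling system,cpd0104
Phosphatidylinositol signaling system,cpd0105
Phosphatidylinositol signaling system,cpd0106
Phosphatidylinositol signaling system,cpd0107
Phosphatidylinositol signaling system,cpd0108
Phosphatidylinositol signaling system,cpd0109
Phosphatidylinositol signaling system,cpd0110
Phosphatidylinositol signaling system,cpd0111
Phosphatidylinositol signaling system,cpd0112
Phosphatidylinositol signaling system,cpd0113
Phosphatidylinositol signaling system,cpd0114
Phosphatidylinositol signaling system,cpd0115
Phosphatidylinositol signaling system,cpd0116
Inositol phosphate metabolism,cpd0117
Inositol phosphate metabolism,cpd0118
Inositol phosphate metabolism,cpd0119
Inositol phosphate metabolism,cpd0120
Inositol phosphate metabolism,cpd0121
Inositol phosphate metabolism,cpd0122
Inositol phosphate metabolism,cpd0123
Inositol phosphate metabolism,cpd0124
Inositol phosphate metabolism,cpd0125
Inositol phosphate metabolism,cpd0126
Inositol phosphate metabolism,cpd0127
Inositol phosphate metabolism,cpd0128
Inositol phosphate metabolism,cpd0129
Inositol phosphate metabolism,cpd0130
Inositol phosphate metabolism,cpd0131
Inositol phosphate metabolism,cpd0132
Inositol phosphate metabolism,cpd0133
Inositol phosphate metabolism,cpd0134
Inositol phosphate metabolism,cpd0135
Inositol phosphate metabolism,cpd0136
Inositol phosphate metabolism,cpd0137
Inositol phosphate metabolism,cpd0138
Inositol phosphate metabolism,cpd0139
Inositol phosphate metabolism,cpd0140
Inositol phosphate metabolism,cpd0141
Inositol phosphate metabolism,cpd0142
Inositol phosphate metabolism,cpd0143
Inositol phosphate metabolism,cpd0144
Inositol phosphate metabolism,cpd0145
Inositol phosphate metabolism,cpd0146
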