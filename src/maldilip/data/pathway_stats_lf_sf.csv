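# Enrichment summary for lipids differentially abundant between large and
# small follicles (total/hits/enrichment/raw Fisher p/topology impact).
pathway,total,hits,enrichment,raw_p,impact
Glycerophospholipid metabolism,36,3,25.8,1.12e-4,0.218
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis,14,2,44.3,7.46e-4,0.004
Sphingolipid metabolism,21,2,29.5,1.71e-3,0.269
Linoleic acid metabolism,5,1,62.0,1.60e-2,0
Alpha-linolenic acid metabolism,13,1,23.8,4.13e-2,0
Phosphatidylinositol signaling system,28,1,11.1,8.72e-2,0.097
Inositol phosphate metabolism,30,1,10.3,9.32e-2,0.078
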