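# Synthetic reconstruction of the 49-compound host-only bacteriocyte medium.
# Assembled from published descriptions of phloem sap and whitefly
# bacteriocyte content: ATP, NAD+ and other cofactors and vitamins (heme,
# thiamine), six non-essential amino acids, sugars, central-carbon
# precursors and inorganics. KEGG-style compound ids; one id per line.
#
# currency / cofactors / vitamins
C00002
C00008
C00003
C00006
C00032
C00378
C00255
C00250
C00864
C00120
C00101
C00010
# non-essential amino acids
C00025
C00049
C00065
C00037
C00097
C00148
# sugars and polyols
C00031
C00095
C00089
C01083
C00121
C00116
C00137
# central-carbon and biosynthetic precursors
C00117
C00279
C00074
C00155
C00022
C00036
C00026
C00042
C00122
C00149
C00092
C00085
C00118
# nucleosides
C00212
C00387
C00299
# inorganics
C00001
C00007
C00011
C00014
C00009
C00013
C00059
C00080
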