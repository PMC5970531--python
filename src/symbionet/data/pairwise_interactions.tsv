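# Published pairwise predictions for the five whitefly-symbiont genera
# (seven genome reconstructions). One ordered pair per line. comp_host /
# comp_hp: number of complementary metabolites in the host-only and
# host+obligate environments (single host-environment value for pairs
# involving the obligate symbiont, comp_hp = NA). competition: effective
# metabolic overlap, the effect of the column species on the row species.
# occurring: 1/0 from a 2030-individual field survey of the unordered pair
# (NA for same-genus genome duplicates), reconstructed best-effort from the
# published table's typography.
row_organism	row_genus	col_organism	col_genus	comp_host	comp_hp	competition	occurring
Hamiltonella_MED-Q1	Hamiltonella	Hamiltonella_MEAM1	Hamiltonella	0	0	0.32	NA
Hamiltonella_MED-Q1	Hamiltonella	Rickettsia_MEAM1-USA	Rickettsia	22	17	0.19	0
Hamiltonella_MED-Q1	Hamiltonella	Rickettsia_MEAM1-China	Rickettsia	21	20	0.2	0
Hamiltonella_MED-Q1	Hamiltonella	Cardinium	Cardinium	0	0	0.08	1
Hamiltonella_MED-Q1	Hamiltonella	Wolbachia	Wolbachia	11	14	0.22	1
Hamiltonella_MED-Q1	Hamiltonella	Portiera	Portiera	13	NA	0.06	1
Hamiltonella_MEAM1	Hamiltonella	Hamiltonella_MED-Q1	Hamiltonella	0	0	0.97	NA
Hamiltonella_MEAM1	Hamiltonella	Rickettsia_MEAM1-USA	Rickettsia	19	20	0.17	1
Hamiltonella_MEAM1	Hamiltonella	Rickettsia_MEAM1-China	Rickettsia	20	21	0.19	1
Hamiltonella_MEAM1	Hamiltonella	Cardinium	Cardinium	0	0	0.05	0
Hamiltonella_MEAM1	Hamiltonella	Wolbachia	Wolbachia	18	7	0.19	0
Hamiltonella_MEAM1	Hamiltonella	Portiera	Portiera	14	NA	0.05	1
Rickettsia_MEAM1-USA	Rickettsia	Hamiltonella_MED-Q1	Hamiltonella	22	17	0.2	0
Rickettsia_MEAM1-USA	Rickettsia	Hamiltonella_MEAM1	Hamiltonella	19	20	0.2	1
Rickettsia_MEAM1-USA	Rickettsia	Rickettsia_MEAM1-China	Rickettsia	0	0	0.95	NA
Rickettsia_MEAM1-USA	Rickettsia	Cardinium	Cardinium	9	9	0.09	0
Rickettsia_MEAM1-USA	Rickettsia	Wolbachia	Wolbachia	6	4	0.11	1
Rickettsia_MEAM1-USA	Rickettsia	Portiera	Portiera	14	NA	0.07	1
Rickettsia_MEAM1-China	Rickettsia	Hamiltonella_MED-Q1	Hamiltonella	21	20	0.21	0
Rickettsia_MEAM1-China	Rickettsia	Hamiltonella_MEAM1	Hamiltonella	20	21	0.21	1
Rickettsia_MEAM1-China	Rickettsia	Rickettsia_MEAM1-USA	Rickettsia	0	0	1	NA
Rickettsia_MEAM1-China	Rickettsia	Cardinium	Cardinium	10	11	0.12	0
Rickettsia_MEAM1-China	Rickettsia	Wolbachia	Wolbachia	8	7	0.14	1
Rickettsia_MEAM1-China	Rickettsia	Portiera	Portiera	13	NA	0.07	1
Cardinium	Cardinium	Hamiltonella_MED-Q1	Hamiltonella	0	0	0.17	1
Cardinium	Cardinium	Hamiltonella_MEAM1	Hamiltonella	0	0	0.15	0
Cardinium	Cardinium	Rickettsia_MEAM1-USA	Rickettsia	9	9	0.1	0
Cardinium	Cardinium	Rickettsia_MEAM1-China	Rickettsia	10	11	0.12	0
Cardinium	Cardinium	Wolbachia	Wolbachia	9	9	0.12	0
Cardinium	Cardinium	Portiera	Portiera	13	NA	0.15	1
Wolbachia	Wolbachia	Hamiltonella_MED-Q1	Hamiltonella	11	14	0.38	1
Wolbachia	Wolbachia	Hamiltonella_MEAM1	Hamiltonella	18	7	0.36	0
Wolbachia	Wolbachia	Rickettsia_MEAM1-USA	Rickettsia	6	4	0.3	1
Wolbachia	Wolbachia	Rickettsia_MEAM1-China	Rickettsia	8	7	0.34	1
Wolbachia	Wolbachia	Cardinium	Cardinium	9	9	0.14	0
Wolbachia	Wolbachia	Portiera	Portiera	8	NA	0.12	1
Portiera	Portiera	Hamiltonella_MED-Q1	Hamiltonella	13	NA	0.25	1
Portiera	Portiera	Hamiltonella_MEAM1	Hamiltonella	14	NA	0.25	1
Portiera	Portiera	Rickettsia_MEAM1-USA	Rickettsia	14	NA	0.25	1
Portiera	Portiera	Rickettsia_MEAM1-China	Rickettsia	13	NA	0.25	1
Portiera	Portiera	Cardinium	Cardinium	13	NA	0.25	1
Portiera	Portiera	Wolbachia	Wolbachia	8	NA	0.25	1
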