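# symbionet

Reverse-ecology analysis of insect endosymbiont communities from genome-derived
metabolic networks. Sap-feeding insects such as the whitefly *Bemisia tabaci*
host an obligate symbiont (*Portiera*) plus varying combinations of facultative
symbionts (*Rickettsia*, *Hamiltonella*, *Cardinium*, *Wolbachia*) inside
bacteriocyte cells. `symbionet` predicts, from each genome's EC-number content
alone:

1. **Metabolic capability** in a bacteriocyte-like environment — which
   essential metabolites each symbiont can synthesize from the compounds the
   host provides;
2. **Complementary (synergistic) metabolites** — compounds only a
   *combination* of genomes can produce, and whether that complementation is
   masked once the obligate symbiont enriches the medium;
3. **Competition** — the asymmetric effective metabolic overlap of every
   ordered genome pair, from topology-derived seed sets;
4. **Nutrient dependencies** — how many essential metabolites each genome
   loses when a single source metabolite is withdrawn.

## Model

An organism's network is the set of catalogued directed reactions matching its
EC numbers (reversible reactions split into both directions). Capability is
computed by **network expansion**: starting from the source metabolites
*S*, repeatedly fire every reaction whose substrates are all available and add
its products, until nothing changes. The result — the *scope*
σ(S, R) — is the unique least fixed point, independent of reaction order; the
model is qualitative (no stoichiometry or flux).

- **Complementary metabolites** of a combination C in environment *S*:
  σ(S, ∪ C) \ ⋃ over proper sub-combinations C′ of σ(S, ∪ C′).
- **Seed set** of a network: all compounds in source strongly-connected
  components of its substrate→product compound graph (the resources the
  organism must import).
- **Competition score** of ordered pair (row, col):
  (T_opt − T_red) / T_opt, where T_opt is the number of essential metabolites
  the row organism produces from its own seed set and T_red the number it
  still produces after the seeds shared with the column organism are removed.
  0 = no overlap, 1 = complete overlap; asymmetric.
- **Dependency cell** (organism, source s): n_produced(S) − n_produced(S\{s}).

## Worked example

Generate the bundled five-genome demonstration community (hand-built around
the packaged 49-compound bacteriocyte medium) and run the full pipeline:

```sh
symbionet simulate --kind demo --out demo
symbionet run --universe demo/universe.tsv --ec-dir demo/ec \
    --environment demo/environment.txt --targets demo/targets.txt \
    --derive-env2-from Portiera --out demo_out
```

`demo_out/summary.tsv` then contains

```
statistic	value
mean_cross_genus_competition	0.5000
```

and `demo_out/complementary_metabolites.tsv` includes the rows

```
combination	environment	n_complementary	complementary
Hamiltonella+Wolbachia	environment	1	C00047
Portiera+Rickettsia	environment	3	C00123;C00183;C00407
Hamiltonella+Wolbachia	environment+Portiera	0	
```

i.e. lysine (C00047) requires the Hamiltonella+Wolbachia pair (Wolbachia
builds M-DAP, Hamiltonella carries the terminal decarboxylase, EC 4.1.1.20),
and the three branched-chain amino acids (valine C00183, leucine C00123,
isoleucine C00407) require the obligate symbiont's intermediates plus the
*Rickettsia*-like aminotransferase (EC 2.6.1.42). In the enriched
host+Portiera environment the lysine row disappears: the complementation is
masked because Hamiltonella can finish lysine from the M-DAP that Portiera
already secretes. `dependency_table.tsv` shows, e.g., that only the
kinase-bearing Wolbachia loses a target when thiamine (C00378) is withdrawn.

The library mirrors the CLI one-to-one (`expand`, `kwise_complementary`,
`masking_classify`, `competition_matrix`, `dependency_scan`, ...); see the
module docstrings.

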