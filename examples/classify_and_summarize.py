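"""Classify simulated collections and summarize per-site statistics.

Simulates two corn-field collection sites with different haplotype
mixtures, runs the COI/Tpi diagnostic-site classification, and prints
the per-site summary: corn-strain frequency, the Z-linked chromosome
estimates, the Tpi corn-allele frequency, and the (h4-h2)/(h2+h4)
population-group contrast (positive values are the TX-type pattern,
negative the FL-type).
"""

from fawkit import markers, popstats, synthdata

refs = markers.load_default_references()

sites = [
    # a TX-type-like site: h4 dominates h2
    synthdata.PopulationSpec(
        site_id="Ecu-Pv", n_specimens=80, seed=1,
        coi_class_probs={"RS": 0.02, "h1": 0.18, "h2": 0.05, "h3": 0.15, "h4": 0.60},
        tpi_R_allele_freq=0.02,
    ),
    # an FL-type-like site: h2 dominates h4
    synthdata.PopulationSpec(
        site_id="FL", n_specimens=60, seed=2,
        coi_class_probs={"RS": 0.05, "h1": 0.20, "h2": 0.55, "h3": 0.10, "h4": 0.10},
        tpi_R_allele_freq=0.10,
    ),
]

calls = []
for spec in sites:
    records, _ = synthdata.simulate_population(spec, refs)
    calls += markers.classify_dataset(records, refs)

table = popstats.tally_calls(calls)
summary = popstats.summarize_dataset(table, txfl_threshold=0.0)
print(summary.round(4).to_string())
print()
print("freq_coi_cs: fraction of corn-strain specimens (h1-h4) among classified COI calls")
print("freq_tpi_c: corn-strain allele frequency on estimated Z chromosomes (1.5*hom + het)")
print("txfl_metric: (h4-h2)/(h2+h4); >= 0 labelled TX-type here, < 0 FL-type")
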