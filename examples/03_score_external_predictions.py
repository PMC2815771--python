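"""Score predictions supplied by an external finder.

Any tool's output can be evaluated once written to the predictions TSV
(columns: dataset_id, finder_id, species, gene, start, end, strand,
site_sequence, score; 0-based half-open coordinates).  MEME plain-text
reports can be converted with motifbench.meme.parse_meme_text.  Here we
fabricate a deliberately imperfect prediction set to show the measures.
"""

from motifbench import (
    PredictedSite,
    PredictionRun,
    simulate_from_config,
    summarize_test,
    write_predictions,
    read_predictions,
)

ds = simulate_from_config(
    {"space": "coregulation", "target_ic": 24.0}, seed=3, dataset_id="demo"
)

# hit 8 of the 10 embedded sites, shifted by 5 bp (still >= half-covering),
# plus two spurious calls
sites = [
    PredictedSite(species=t.species, gene=t.gene, start=t.start + 5, end=t.end + 5,
                  sequence=ds.record(t.species, t.gene).sequence[t.start + 5:t.end + 5])
    for t in ds.sites[:8]
]
sites += [
    PredictedSite(species="REF", gene=g, start=0, end=13,
                  sequence=ds.record("REF", g).sequence[0:13])
    for g in ("g8", "g9")
]
run = PredictionRun("demo", "external", has_output=True, sites=sites)

write_predictions([run], "scratch/external_pred.tsv")
runs = read_predictions("scratch/external_pred.tsv")
s = summarize_test(runs, ds)

print(f"runs with output (D1): {s.d1_or_r1} of {s.n_runs}")
print(f"recovery rate (RR):    {s.rr:.0f}%")
print(f"mean PPV:              {s.ppv:.1f}%")
print(f"mean Sens:             {s.sens:.1f}%")
print(f"F-value:               {s.f_value:.1f}%  (harmonic mean of spPPV and spSens)")
# The 5 bp shift keeps each prediction covering >= 6.5 of the 13 bp
# truth, so the 8 shifted calls are TPs; the two start-of-sequence calls
# are FPs unless a site happens to sit there.
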