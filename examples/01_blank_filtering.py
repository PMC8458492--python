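"""Blank-filter a synthetic feature table against saline method blanks.

Generates a small study in which each chemical contributes one feature per
EI fragment and 60 background contaminant features appear in every
injection, then removes everything whose nonblank mean intensity is not
more than 10x the method-blank mean.
"""

from gcexpose import NoiseModel, blank_filter, make_universe, simulate_study

noise = NoiseModel(seed=0)
chemicals, library, references = make_universe(15, (4, 6), noise)
table, truth = simulate_study(chemicals, n_study_samples=20, noise=noise)

filtered, report = blank_filter(table, fold=10)

print(f"features before filtering: {report.n_features_before}")
print(f"features after filtering:  {report.n_features_after}")
print(f"removed (blank-level):     {len(report.removed_features)}")
planted = set(truth.feature_map["feature_id"])
kept = set(filtered.feature_ids)
print(f"planted chemical features retained: {len(kept & planted)}/{len(planted)}")
print(f"background features retained:       {len(kept - planted)}")
# The filter should keep every planted fragment feature (absent from the
# blanks) and discard the background features present in all injections.
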