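"""Identify library chemicals by co-eluting accurate-mass fragments.

Plants 10 of 20 library chemicals into a study at realistic m/z and
retention-time jitter, then requires >= 3 fragments within +/-5 ppm and
30 s of the library values for a positive identification.  The 10 decoy
chemicals (in the library, absent from the data) must not be identified.
"""

from gcexpose import NoiseModel, make_universe, match_all, simulate_study

noise = NoiseModel(seed=1, ppm_sigma=1.5, rt_sigma=5.0 / 60.0)
chemicals, library, _ = make_universe(20, (4, 6), noise)
planted = [c.chemical_name for c in chemicals[:10]]
table, truth = simulate_study(chemicals, 12, noise=noise, planted=planted)

results, conflicts = match_all(table, library, ppm_tol=5, rt_tol_s=30, min_fragments=3)

identified = sorted(r.chemical_name for r in results if r.identified)
print(f"identified {len(identified)}/{len(planted)} planted chemicals: {identified}")
decoy_hits = set(identified) - set(planted)
print(f"decoy chemicals wrongly identified: {len(decoy_hits)}")
for r in results[:3]:
    if r.identified:
        worst = max(abs(m.ppm_error) for m in r.matched_fragments)
        print(
            f"  {r.chemical_name}: {r.n_fragments_matched} fragments, "
            f"max |ppm error| {worst:.2f}, quantifier {r.quantifier_feature}"
        )
# Every planted chemical should be found with all fragments inside the
# tolerance windows; decoys stay at zero.
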