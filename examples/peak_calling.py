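"""Signal-block peak calling: numeric threshold and control-calibrated.

Builds one sample's coverage track, segments it into maximal positive
signal blocks, and calls peaks two ways: keeping the top 0.1% of blocks
by total signal (the suspect-list setting), and thresholding a target
against a matched control at an empirical control quantile.
"""

import crsuspect as cs

cfg = cs.SimulationConfig(seed=4)
panel, truth = cs.simulate_negative_panel(cfg)
frags = panel[0]

track = cs.fragments_to_coverage(frags, cfg.layout)
blocks = cs.find_signal_blocks(track)
print(f"{len(frags)} fragments -> {len(blocks)} signal blocks "
      f"(total signal {track.total_auc:.0f} bp x coverage)")

peaks = cs.call_peaks_numeric(blocks, cs.PeakCallParams(threshold=0.001,
                                                        mode="stringent"))
print(f"top 0.1% by AUC (stringent): {len(peaks)} peaks; "
      f"strongest AUC = {peaks.data['auc'].max():.0f}")

target, control, truth2 = cs.simulate_target_experiment(cfg, n_sites=40,
                                                        site_fold=100.0)
t_blocks = cs.find_signal_blocks(cs.fragments_to_coverage(target, cfg.layout))
c_blocks = cs.find_signal_blocks(cs.fragments_to_coverage(control, cfg.layout))
called = cs.call_peaks_vs_control(
    t_blocks, c_blocks,
    cs.PeakCallParams(threshold=0.01, mode="stringent", normalize=True))
print(f"\ntarget vs control at the 99th control percentile: {len(called)} peaks")
print("(these include the planted binding sites AND the shared artifact "
      "regions -- see qc_evaluation.py for why the artifacts must go)")
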