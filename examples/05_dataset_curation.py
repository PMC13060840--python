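"""Curate an ensemble training set and an apo-holo evaluation set.

Mirrors the corpus construction used for ensemble-aware training: split
multi-model depositions, drop entries over 256 residues, exclude training
sequences >70% identical to the test set, crop to 256 residues, and pair
each cropped conformer with the P(r) of exactly its cropped coordinates.
"""

import saxsfold as sf

config = sf.CurationConfig(seed=0)

ensembles = [
    sf.ConformerEnsemble(name, sf.make_nmr_ensemble(
        sf.FixtureSpec(kind="nmr_ensemble", n_residues=n, n_models=5,
                       noise=0.3, seed=i)).models)
    for i, (name, n) in enumerate([("entryA", 120), ("entryB", 256), ("entryC", 300)])
]

kept, dropped = sf.filter_length(ensembles, config)
print(f"length filter (>256 dropped): kept {[e.entry_id for e in kept]}, "
      f"dropped {[d['entry_id'] for d in dropped]}")

train = [(e.entry_id, e.sequence) for e in kept]
test = [("testX", kept[0].sequence)]   # test entry identical to entryA
survivors, excluded = sf.exclude_similar(train, test, config)
print(f"similarity filter (>70% excluded): kept {[t for t, _ in survivors]}, "
      f"excluded {[x['entry_id'] for x in excluded]} "
      f"at {[round(x['identity'], 1) for x in excluded]}% identity")

records = sf.build_training_records(kept[1], config)
print(f"training records for {kept[1].entry_id}: {len(records)} conformers, "
      f"crop window {records[0].crop_window}, "
      f"P(r) bins {len(records[0].pr.r)} (recomputed from the crop)")

candidates = [
    sf.ApoHoloCandidate("pair1", 200, 5.2, (3.1, 2.8)),
    sf.ApoHoloCandidate("pair2", 200, 3.0, (3.1, 2.8)),   # too similar states
    sf.ApoHoloCandidate("pair3", 300, 5.2, (3.1, 2.8)),   # too long
]
selected, _ = sf.select_apo_holo_targets(candidates, config)
print(f"apo-holo targets (pair RMSD>4, conformer RMSD>2.5, length<=256): "
      f"{[c.pair_id for c in selected]}")
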