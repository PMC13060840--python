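"""Dataset curation: model splitting, filters, cropping, record pairing."""

import numpy as np
import pytest
from scipy import stats as sps

from saxsfold import (
    ApoHoloCandidate,
    AtomicStructure,
    ConformerEnsemble,
    CurationConfig,
    FixtureSpec,
    build_training_records,
    compute_pr,
    crop_random,
    exclude_similar,
    filter_length,
    make_chain,
    make_nmr_ensemble,
    select_apo_holo_targets,
    sequence_identity,
    split_models,
    write_pdb,
)
from saxsfold.errors import DegenerateInputError, MalformedEnsembleError
from oracles import needleman_wunsch_identities


def _ensemble(n_res, n_models=3, seed=0, entry="e"):
    ens = make_nmr_ensemble(FixtureSpec(kind="nmr_ensemble", n_residues=n_res,
                                        n_models=n_models, noise=0.2, seed=seed))
    return ConformerEnsemble(entry, ens.models)


class TestSplitModels:
    def test_twenty_model_file(self, tmp_path):
        ens = _ensemble(20, n_models=20)
        path = tmp_path / "ens.pdb"
        write_pdb(ens, path)
        out = split_models(path)
        assert out.n_models == 20
        assert [m.model_id for m in out.models] == list(range(1, 21))

    def test_single_model_file(self, tmp_path):
        st = make_chain(FixtureSpec(kind="helix", n_residues=12, seed=0))
        path = tmp_path / "one.pdb"
        write_pdb(st, path)
        assert split_models(path).n_models == 1

    def test_mutated_model_rejected(self, tmp_path):
        ens = _ensemble(15, n_models=8)
        bad = ens.models[6]
        bad.res_names[4] = "TRP" if bad.res_names[4] != "TRP" else "GLY"
        path = tmp_path / "bad.pdb"
        # bypass the constructor check to write the inconsistent file
        obj = ConformerEnsemble.__new__(ConformerEnsemble)
        obj.entry_id, obj.models = "bad", ens.models
        write_pdb(obj, path)
        with pytest.raises(MalformedEnsembleError):
            split_models(path)


class TestFilterLength:
    def test_thresholds_are_strict(self):
        batch = [_ensemble(n, entry=f"len{n}") for n in (100, 256, 257)]
        config = CurationConfig()
        kept, dropped = filter_length(batch, config)
        assert [e.entry_id for e in kept] == ["len100", "len256"]
        assert len(dropped) == 1 and dropped[0]["entry_id"] == "len257"

    def test_oversized_entry_dropped_with_reason(self):
        kept, dropped = filter_length([_ensemble(300, entry="big")], CurationConfig())
        assert not kept
        assert "300" in dropped[0]["reason"]


class TestSequenceIdentity:
    def test_identical(self):
        assert sequence_identity("ACDEFGHIK", "ACDEFGHIK") == 100.0

    def test_disjoint_alphabets(self):
        assert sequence_identity("AAAA", "GGGG") == 0.0

    def test_matches_needleman_wunsch_oracle(self):
        # co-optimal alignments can differ in identity; the value must lie in
        # the set produced by enumerating every score-optimal alignment
        a, b = "HEAGAWGHEE", "PAWHEAE"
        valid = needleman_wunsch_identities(a, b)
        assert any(sequence_identity(a, b) == pytest.approx(v) for v in valid)

    @pytest.mark.parametrize("a,b", [
        ("MKTAYIAKQR", "MKTAYIAKQR"),
        ("MKTAYIAKQR", "MKTAYIA"),
        ("ACACACAC", "GTGTGTGT"),
        ("WWWWHHHH", "HHHHWWWW"),
    ])
    def test_symmetry(self, a, b):
        assert sequence_identity(a, b) == pytest.approx(sequence_identity(b, a))

    def test_empty_refused(self):
        with pytest.raises(DegenerateInputError):
            sequence_identity("", "ACD")


class TestExcludeSimilar:
    def test_identical_entry_excluded(self):
        config = CurationConfig()
        kept, excluded = exclude_similar(
            [("t1", "MKTAYIAKQRQISFVK")], [("q1", "MKTAYIAKQRQISFVK")], config)
        assert not kept
        assert excluded[0]["identity"] == 100.0

    def test_disjoint_alphabet_all_kept(self):
        config = CurationConfig()
        train = [("t1", "AAAAAAAA"), ("t2", "CCCCCCCC")]
        kept, excluded = exclude_similar(train, [("q", "GGGGGGGG")], config)
        assert kept == train and not excluded

    def test_exclusion_matches_hand_computation(self):
        config = CurationConfig()
        test = [("q", "AAAAAAAAAA")]
        # identities to "q": computed by the DP oracle, straddling 70%
        train = [
            ("hi", "AAAAAAAAAC"),   # 90% -> excluded
            ("mid", "AAAAAAACCC"),  # 70% -> kept (strict >)
            ("lo", "AAAACCCCCC"),   # 40% -> kept
        ]
        for tid, seq in train:
            valid = needleman_wunsch_identities(seq, test[0][1])
            assert any(sequence_identity(seq, test[0][1]) == pytest.approx(v)
                       for v in valid)
        kept, excluded = exclude_similar(train, test, config)
        assert [t for t, _ in kept] == ["mid", "lo"]
        assert excluded[0]["entry_id"] == "hi"


class TestCropRandom:
    def test_short_structure_returned_whole(self):
        st = make_chain(FixtureSpec(kind="helix", n_residues=100, seed=0))
        cropped, window = crop_random(st, CurationConfig())
        assert cropped.n_residues == 100
        assert window == (1, 100)

    def test_deterministic_window(self):
        st = make_chain(FixtureSpec(kind="helix", n_residues=300, seed=0))
        config = CurationConfig(seed=11)
        a = crop_random(st, config)
        b = crop_random(st, config)
        assert a[1] == b[1]
        assert a[0].n_residues == 256
        assert (a[0].coords == b[0].coords).all()

    def test_start_distribution_uniform(self):
        st = make_chain(FixtureSpec(kind="helix", n_residues=60, seed=0))
        config = CurationConfig(crop_length=50)
        starts = [crop_random(st, config, seed=s)[1][0] for s in range(10_000)]
        counts = np.bincount(starts, minlength=12)[1:12]  # starts 1..11
        assert sps.chisquare(counts).pvalue > 0.01


class TestTrainingRecords:
    def test_one_record_per_model_with_distinct_curves(self):
        ens = _ensemble(30, n_models=20, seed=3)
        records = build_training_records(ens, CurationConfig())
        assert len(records) == 20
        curves = [r.pr.p for r in records]
        assert any(not np.array_equal(curves[0], c) for c in curves[1:])

    def test_duplicate_models_give_identical_curves(self):
        base = make_chain(FixtureSpec(kind="helix", n_residues=25, seed=1))
        ens = ConformerEnsemble("dup", [
            AtomicStructure.from_ca(base.coords, base.sequence(), model_id=i + 1)
            for i in range(3)
        ])
        records = build_training_records(ens, CurationConfig())
        assert all((r.pr.p == records[0].pr.p).all() for r in records)

    def test_curves_match_standalone_recomputation(self):
        ens = _ensemble(40, n_models=5, seed=7)
        config = CurationConfig(dr=0.5)
        for rec in build_training_records(ens, config):
            standalone = compute_pr(rec.structure, dr=0.5, normalize=True)
            assert (rec.pr.p == standalone.p).all()

    def test_reproducible_from_provenance(self):
        ens = _ensemble(300, n_models=3, seed=9)
        config = CurationConfig(seed=21)
        first = build_training_records(ens, config)
        second = build_training_records(ens, config)
        for a, b in zip(first, second):
            assert a.crop_window == b.crop_window
            assert (a.pr.p == b.pr.p).all()


class TestApoHoloSelection:
    CASES = [
        (ApoHoloCandidate("keep", 200, 5.0, (3.0, 3.0)), True),
        (ApoHoloCandidate("low_pair", 200, 3.9, (3.0, 3.0)), False),
        (ApoHoloCandidate("long", 300, 5.0, (3.0, 3.0)), False),
        (ApoHoloCandidate("low_conf", 200, 5.0, (3.0, 2.0)), False),
        (ApoHoloCandidate("edge_pair", 200, 4.0, (3.0, 3.0)), False),   # strict >
        (ApoHoloCandidate("edge_conf", 200, 5.0, (2.5, 3.0)), False),   # strict >
        (ApoHoloCandidate("edge_len", 256, 4.1, (2.6, 2.6)), True),     # <= 256 kept
        (ApoHoloCandidate("big_all", 100, 12.0, (8.0, 9.0)), True),
        (ApoHoloCandidate("barely", 256, 4.001, (2.501, 2.501)), True),
        (ApoHoloCandidate("nope", 257, 4.001, (2.501, 2.501)), False),
    ]

    def test_selection_matches_hand_rules(self):
        candidates = [c for c, _ in self.CASES]
        expected = [c.pair_id for c, keep in self.CASES if keep]
        selected, report = select_apo_holo_targets(candidates, CurationConfig())
        assert [c.pair_id for c in selected] == expected
        assert len(report) == len(candidates) - len(expected)


def test_curation_is_idempotent():
    """Re-running length filtering and selection on their own output is a no-op."""
    config = CurationConfig()
    batch = [_ensemble(n, entry=f"e{n}") for n in (50, 256, 290)]
    kept, _ = filter_length(batch, config)
    again, dropped = filter_length(kept, config)
    assert [e.entry_id for e in again] == [e.entry_id for e in kept] and not dropped
    candidates = [c for c, _ in TestApoHoloSelection.CASES]
    selected, _ = select_apo_holo_targets(candidates, config)
    twice, report = select_apo_holo_targets(selected, config)
    assert twice == selected and not report
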