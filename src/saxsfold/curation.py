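"""Training- and target-dataset curation.

Mirrors the construction of an ensemble training corpus from multi-model
(solution NMR) depositions and of an apo-holo evaluation set:

* split multi-model files into individual conformers;
* drop entries longer than 256 residues;
* exclude training entries with more than 70% global-alignment sequence
  identity to any test entry (leakage control);
* crop each conformer to a contiguous window of at most 256 residues,
  uniformly at random under a seed;
* pair every cropped conformer with the P(r) curve computed from exactly its
  cropped coordinates;
* keep apo-holo candidate pairs whose conformational change is large enough
  to be interesting (pair RMSD > 4 A, per-conformer baseline RMSD > 2.5 A)
  and whose length fits the crop budget.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .errors import DegenerateInputError
from .profile import DEFAULT_DR, PrCurve, compute_pr
from .structures import AtomicStructure, ConformerEnsemble


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds and knobs of the curation pipeline."""

    max_residues: int = 256
    similarity_threshold: float = 70.0   # percent identity, strict '>' excludes
    crop_length: int = 256
    pair_rmsd_min: float = 4.0           # Angstrom, strict '>'
    conformer_rmsd_min: float = 2.5      # Angstrom, strict '>'
    dr: float = DEFAULT_DR
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_residues, self.crop_length) < 1:
            raise DegenerateInputError("length thresholds must be positive")
        if min(self.similarity_threshold, self.pair_rmsd_min, self.conformer_rmsd_min) <= 0:
            raise DegenerateInputError("thresholds must be positive")


def split_models(source) -> ConformerEnsemble:
    """One conformer per MODEL block of a multi-model structure file.

    ``source`` is a path (delegated to the structure reader) or an already
    parsed ensemble/structure.  Models must agree in sequence; a mismatch
    raises a malformed-ensemble error.
    """
    if isinstance(source, ConformerEnsemble):
        return ConformerEnsemble(source.entry_id, list(source.models))
    if isinstance(source, AtomicStructure):
        return ConformerEnsemble("entry", [source])
    from .io import read_structure  # deferred: io imports this module's types

    parsed = read_structure(source)
    if isinstance(parsed, AtomicStructure):
        return ConformerEnsemble(str(source), [parsed])
    return parsed


def filter_length(
    ensembles: Iterable[ConformerEnsemble],
    config: CurationConfig,
) -> tuple[list[ConformerEnsemble], list[dict]]:
    """Drop entries with more residues than the training crop can represent.

    The reading is strict: an entry of exactly ``max_residues`` residues is
    kept.  Returns the kept list and a per-dropped-entry report.
    """
    kept, dropped = [], []
    for ens in ensembles:
        n = ens.n_residues
        if n > config.max_residues:
            dropped.append({
                "entry_id": ens.entry_id, "n_residues": n,
                "reason": f"n_residues {n} > {config.max_residues}",
            })
        else:
            kept.append(ens)
    return kept, dropped


def _aligner() -> Align.PairwiseAligner:
    # unit match, zero mismatch, linear gap -1: a plain identity-style scoring
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


def sequence_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Identity = identical aligned positions / alignment length (columns,
    including gaps) * 100, under unit-match / zero-mismatch / linear-gap(-1)
    scoring.  Symmetric in its arguments.
    """
    if not a or not b:
        raise DegenerateInputError("empty sequence")
    alignment = _aligner().align(a, b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


def exclude_similar(
    train_entries: Sequence[tuple[str, str]],
    test_entries: Sequence[tuple[str, str]],
    config: CurationConfig,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Leakage filter: drop a training entry if its identity to ANY test
    sequence strictly exceeds the threshold.

    Entries are (id, sequence) pairs.  Returns kept entries and an exclusion
    report naming the offending test entry and identity.
    """
    kept, excluded = [], []
    for tid, tseq in train_entries:
        hit = None
        for qid, qseq in test_entries:
            ident = sequence_identity(tseq, qseq)
            if ident > config.similarity_threshold:
                hit = {"entry_id": tid, "test_id": qid, "identity": ident}
                break
        if hit is None:
            kept.append((tid, tseq))
        else:
            excluded.append(hit)
    return kept, excluded


def crop_random(
    structure: AtomicStructure,
    config: CurationConfig,
    seed: int | None = None,
) -> tuple[AtomicStructure, tuple[int, int]]:
    """Contiguous random residue crop of at most ``crop_length`` residues.

    The window start is uniform under the seed; structures no longer than the
    crop length are returned whole.  The returned window is 1-based and
    inclusive on both ends, in residue order.
    """
    n = structure.n_residues
    if n < 1:
        raise DegenerateInputError("empty structure")
    length = min(config.crop_length, n)
    if length == n:
        start = 0
    else:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        start = int(rng.integers(0, n - length + 1))
    # map residue order positions -> atom mask
    keys: list[tuple[str, int]] = []
    for c, r in zip(structure.chain_ids, structure.res_indices):
        key = (c, int(r))
        if key not in keys:
            keys.append(key)
    window_keys = set(keys[start:start + length])
    mask = np.array([
        (c, int(r)) in window_keys
        for c, r in zip(structure.chain_ids, structure.res_indices)
    ])
    idx = np.where(mask)[0]
    cropped = AtomicStructure(
        elements=[structure.elements[i] for i in idx],
        z=structure.z[idx],
        coords=structure.coords[idx],
        chain_ids=[structure.chain_ids[i] for i in idx],
        res_indices=structure.res_indices[idx],
        res_names=[structure.res_names[i] for i in idx],
        atom_names=[structure.atom_names[i] for i in idx],
        model_id=structure.model_id,
    )
    return cropped, (start + 1, start + length)


@dataclass
class TrainingRecord:
    """One conformer paired with the P(r) of exactly its cropped coordinates."""

    entry_id: str
    model_id: int
    crop_window: tuple[int, int]
    structure: AtomicStructure
    pr: PrCurve
    msa_path: str | None = None   # slot for an externally built alignment


def build_training_records(
    ensemble: ConformerEnsemble,
    config: CurationConfig,
) -> list[TrainingRecord]:
    """One training record per conformer.

    Every model of the entry receives the same crop window (derived from the
    entry seed) so conformers stay comparable, and its P(r) is recomputed
    from the cropped coordinates — the profile always matches the structure
    it is paired with.
    """
    digest = zlib.crc32(ensemble.entry_id.encode())  # stable across processes
    entry_seed = (config.seed + digest) % (2 ** 31)
    records = []
    for model in ensemble.models:
        cropped, window = crop_random(model, config, seed=entry_seed)
        pr = compute_pr(cropped, dr=config.dr, normalize=True)
        records.append(TrainingRecord(
            entry_id=ensemble.entry_id, model_id=model.model_id,
            crop_window=window, structure=cropped, pr=pr,
        ))
    return records


@dataclass(frozen=True)
class ApoHoloCandidate:
    """One candidate pair with its precomputed benchmark RMSD columns."""

    pair_id: str
    n_residues: int
    pair_rmsd: float                      # RMSD between the two states
    conformer_rmsds: tuple[float, ...]    # baseline-vs-conformer RMSD per state


def select_apo_holo_targets(
    candidates: Iterable[ApoHoloCandidate],
    config: CurationConfig,
) -> tuple[list[ApoHoloCandidate], list[dict]]:
    """Evaluation-set selection.

    A pair survives iff its length fits the crop budget (<= max_residues),
    the two states differ by more than ``pair_rmsd_min``, and every
    per-conformer baseline RMSD exceeds ``conformer_rmsd_min`` (the baseline
    predicts neither state well).  Returns selected pairs and a drop report.
    """
    selected, report = [], []
    for cand in candidates:
        reasons = []
        if cand.n_residues > config.max_residues:
            reasons.append(f"n_residues {cand.n_residues} > {config.max_residues}")
        if not cand.pair_rmsd > config.pair_rmsd_min:
            reasons.append(f"pair_rmsd {cand.pair_rmsd} <= {config.pair_rmsd_min}")
        if not all(r > config.conformer_rmsd_min for r in cand.conformer_rmsds):
            reasons.append(f"conformer_rmsd <= {config.conformer_rmsd_min}")
        if reasons:
            report.append({"pair_id": cand.pair_id, "reasons": reasons})
        else:
            selected.append(cand)
    return selected, report
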