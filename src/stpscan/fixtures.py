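"""Deterministic synthetic peptide generator for pipeline testing.

Real training data for this problem are cysteine-rich toxin chains
(knottins, cyclotides, non-knotted STPs) against a background of small
PDB proteins. This module emulates only what the classifier actually
consumes — cysteine geometry, chain length, residue frequencies — so
every stage of the pipeline can be exercised without any download:

* positives carry exactly six cysteines arranged as a valid STP motif:
  the minimum loop (<= 3 residues) sits at C3-C4 and both C-terminal
  loops contain at least one residue; lengths follow the positive
  class's reported profile (mean 42.2, sd 15.7, range 23-143);
* negatives mix (a) random peptides with 0-6 unconstrained cysteines,
  (b) ferredoxin-like decoys whose short CXC/CXXC spacing sits among
  the first cysteine pairs, and (c) six-cysteine chains whose loops
  are all longer than three residues — none passes the motif grammar;
  lengths follow the negative profile (mean 63.2, sd 25.9, range
  9-160);
* "hard mode" negatives DO pass the motif grammar but with proximity
  lengths drawn far more broadly than the positives', so the classes
  are no longer separated by the validity bit alone and the proximity
  features must carry the signal.

Background composition is uniform over the 19 non-cysteine standard
residues; cysteines are only ever placed deliberately.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import motif as motif_mod
from .sequence_io import PeptideSequence, write_fasta

NON_CYS = "ADEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    n_pos: int = 144
    n_neg: int = 393
    seed: int = 0
    pos_length_range: tuple[int, int] = (23, 143)
    neg_length_range: tuple[int, int] = (9, 160)
    pos_length_mean: float = 42.2
    pos_length_sd: float = 15.7
    neg_length_mean: float = 63.16
    neg_length_sd: float = 25.92
    decoy_fraction: float = 0.3
    big_loop_fraction: float = 0.2
    hard: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (self.pos_length_range, self.neg_length_range):
            if lo > hi or lo < 1:
                raise ValueError("inconsistent length range")
        for f in (self.decoy_fraction, self.big_loop_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")


def _draw_length(rng, mean, sd, lo, hi) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


def _fill(rng, n: int) -> str:
    return "".join(rng.choice(list(NON_CYS), size=n)) if n > 0 else ""


def _chain_from_loops(rng, loops, target_len, lo, hi) -> str:
    """Assemble C...C with the given inter-cysteine loops plus flanks."""
    span = len(loops) + 1 + sum(loops)
    total = int(np.clip(target_len, max(lo, span + 2), hi))
    rem = max(total - span, 2)
    n_term = int(rng.integers(1, rem))
    c_term = rem - n_term
    parts = [_fill(rng, n_term)]
    for loop in loops:
        parts.append("C")
        parts.append(_fill(rng, loop))
    parts.append("C")
    parts.append(_fill(rng, c_term))
    return "".join(parts)


def _stp_loops(rng, min_pair: int, loop_cap: int) -> list[int]:
    """Six-cysteine loops with a unique minimum (<= 3) at ``min_pair``."""
    v = int(rng.integers(0, 4))
    loops = [int(rng.integers(v + 1, v + 1 + loop_cap)) for _ in range(5)]
    loops[min_pair] = v
    return loops


def generate_positives(spec: FixtureSpec) -> list[PeptideSequence]:
    """STP-like chains; every one passes the motif grammar as valid."""
    rng = np.random.default_rng([spec.seed, 1])
    lo, hi = spec.pos_length_range
    out = []
    for i in range(spec.n_pos):
        loops = _stp_loops(rng, min_pair=2, loop_cap=12)
        target = _draw_length(rng, spec.pos_length_mean, spec.pos_length_sd, lo, hi)
        out.append(
            PeptideSequence(f"pos_{i:04d}", _chain_from_loops(rng, loops, target, lo, hi))
        )
    return out


def _random_negative(rng, target, lo, hi) -> str:
    """Random peptide with 0-6 cysteines at unconstrained positions."""
    n = int(np.clip(target, lo, hi))
    res = list(_fill(rng, n))
    k = int(rng.integers(0, 7))
    for pos in rng.choice(n, size=min(k, n), replace=False):
        res[pos] = "C"
    return "".join(res)


def generate_negatives(spec: FixtureSpec) -> list[PeptideSequence]:
    """Chains that fail the motif grammar (or, in hard mode, pass it
    with proximity geometry far from the positive profile)."""
    rng = np.random.default_rng([spec.seed, 2])
    lo, hi = spec.neg_length_range
    out = []
    for i in range(spec.n_neg):
        target = _draw_length(rng, spec.neg_length_mean, spec.neg_length_sd, lo, hi)
        if spec.hard:
            # grammar-valid geometry, loops up to 30 residues: P_j ranges
            # far beyond the positives' tight 1-12 loop profile
            loops = _stp_loops(rng, min_pair=2, loop_cap=30)
            residues = _chain_from_loops(rng, loops, target, lo, hi)
        else:
            u = rng.random()
            if u < spec.decoy_fraction:
                # ferredoxin-like: shortest loop among the first two pairs
                loops = _stp_loops(rng, min_pair=int(rng.integers(0, 2)), loop_cap=12)
                residues = _chain_from_loops(rng, loops, target, lo, hi)
            elif u < spec.decoy_fraction + spec.big_loop_fraction:
                loops = [int(rng.integers(4, 16)) for _ in range(5)]
                residues = _chain_from_loops(rng, loops, target, lo, hi)
            else:
                residues = _random_negative(rng, target, lo, hi)
                # a 6-cysteine random draw can pass the grammar by chance
                while motif_mod.anchor_motif(
                    [j + 1 for j, ch in enumerate(residues) if ch == "C"]
                ).valid:
                    residues = _random_negative(rng, target, lo, hi)
        out.append(PeptideSequence(f"neg_{i:04d}", residues))
    return out


def shuffle_labels(
    pos: list[PeptideSequence], neg: list[PeptideSequence], seed: int
) -> tuple[list[PeptideSequence], list[PeptideSequence]]:
    """Randomly reassign class labels, preserving class sizes.

    The no-signal control: any classifier evaluated on the shuffled
    dataset should do no better than chance (AUC about 0.5).
    """
    rng = np.random.default_rng(seed)
    chains = pos + neg
    labels = np.r_[np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)]
    rng.shuffle(labels)
    return (
        [s for s, y in zip(chains, labels) if y == 1],
        [s for s, y in zip(chains, labels) if y == 0],
    )


def generate_dataset(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write pos.fasta, neg.fasta and a manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pos = generate_positives(spec)
    neg = generate_negatives(spec)
    write_fasta(pos, out_dir / "pos.fasta")
    write_fasta(neg, out_dir / "neg.fasta")
    manifest = {
        "spec": asdict(spec),
        "n_pos": len(pos),
        "n_neg": len(neg),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
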