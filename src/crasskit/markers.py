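"""Marker-protein package data and profile construction.

The five genome-structure landmarks (IHF_54, MCP, portal, TerL, primase),
the two crAssphage signature proteins (UGP_018 polymerase, UGP_092
terminase), and the suppressor-tRNA template ship as synthetic package data:
fixed sequences that play the role their natural counterparts play in the
detect -> classify -> annotate logic, without copying any database record.
"""

from __future__ import annotations

import functools
from importlib import resources
from typing import Dict, List

import numpy as np

from .pssm import AA, Profile, build_profile
from .records import ProteinRecord
from Bio.SeqIO.FastaIO import SimpleFastaParser

MARKER_NAMES = ("IHF_54", "MCP", "portal", "TerL", "primase")
STRUCTURAL_MARKERS = ("TerL", "portal", "MCP")
SIGNATURE_NAMES = ("UGP_018", "UGP_092")

#: 0-based offset of the anticodon within the tRNA template
TRNA_ANTICODON_OFFSET = 33


def _read_data_fasta(name: str) -> Dict[str, str]:
    text = resources.files("crasskit.data").joinpath(name).read_text()
    out = {}
    from io import StringIO
    for title, seq in SimpleFastaParser(StringIO(text)):
        out[title.split()[0]] = seq.upper()
    return out


@functools.lru_cache(maxsize=1)
def marker_consensus() -> Dict[str, str]:
    return _read_data_fasta("marker_consensus.fasta")


@functools.lru_cache(maxsize=1)
def signature_proteins() -> Dict[str, ProteinRecord]:
    return {name: ProteinRecord(id=name, seq=seq)
            for name, seq in _read_data_fasta("signatures.fasta").items()}


@functools.lru_cache(maxsize=1)
def trna_template() -> str:
    (seq,) = _read_data_fasta("trna_template.fasta").values()
    return seq


def seed_alignment(consensus: str, *, n: int = 8, divergence: float = 0.15,
                   seed: int = 0) -> List[str]:
    """Deterministic pseudo-seed alignment: n copies of the consensus, each
    with ``divergence`` of positions substituted."""
    rng = np.random.default_rng(seed)
    ncols = len(consensus)
    cons_idx = np.array([AA.index(c) for c in consensus])
    rows = []
    for _ in range(n):
        idx = cons_idx.copy()
        mut = rng.random(ncols) < divergence
        idx[mut] = (idx[mut] + rng.integers(1, 20, int(mut.sum()))) % 20
        rows.append("".join(AA[i] for i in idx))
    return rows


@functools.lru_cache(maxsize=1)
def marker_profiles() -> Dict[str, Profile]:
    """Calibrated PSSM profiles for the five landmark proteins.

    Built once per process; calibration seeds are fixed per marker so the
    thresholds are reproducible bytes-for-bytes.
    """
    profiles = {}
    for i, name in enumerate(MARKER_NAMES):
        cons = marker_consensus()[name]
        seeds = seed_alignment(cons, seed=1000 + i)
        profiles[name] = build_profile(name, seeds, calibration_seed=2000 + i)
    return profiles


@functools.lru_cache(maxsize=1)
def structural_profiles() -> Dict[str, Profile]:
    """The three conserved structural-protein profiles used for detection."""
    all_profiles = marker_profiles()
    return {name: all_profiles[name] for name in STRUCTURAL_MARKERS}
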