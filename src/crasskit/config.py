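"""Single source of truth for every decision threshold in the pipeline.

Every gate used anywhere in the package (viral-contig retention, crAss
signature hits, vOTU clustering, Acr filtering, spacer matching, read
mapping, coverage gating, association significance) resolves to exactly one
field of :class:`ThresholdConfig`, so a change here propagates everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields


@dataclass(frozen=True)
class ThresholdConfig:
    """Decision thresholds for the crAss-like phage pipeline.

    Defaults are the published gut-virome conventions: VirSorter2 /
    DeepVirFinder retention scores, the 70 kb crAss genome floor, MIUViG
    species-rank clustering (95% ANI over >=85% aligned fraction), the
    <=200 aa anti-CRISPR size cap, the one-mismatch CRISPR spacer rule, and
    CoverM-style RPKM gates (90% identity, 95% read aligned, 75% genome
    covered).
    """

    # viral-contig retention (predictor score gates)
    vs2_hi: float = 0.9
    vs2_lo: float = 0.7
    dvf_hi: float = 0.9
    dvf_lo: float = 0.7
    dvf_p_hi: float = 0.01
    dvf_p_lo: float = 0.05
    # signature-protein route
    sig_evalue: float = 1e-5
    sig_minlen: int = 350          # aligned residues
    crass_min_genome: int = 70_000  # bases
    # vOTU clustering
    ani_thresh: float = 95.0       # percent
    af_thresh: float = 85.0        # percent of the shorter genome
    # anti-CRISPR filtering
    acr_maxlen: int = 200          # residues
    # CRISPR spacer -> phage matching
    spacer_max_mismatch: int = 1
    # read mapping / quantification
    read_min_identity: float = 90.0     # percent
    read_min_aligned: float = 95.0      # percent of read length
    min_covered_fraction: float = 75.0  # percent of genome
    # association testing
    assoc_q: float = 0.05

    def __post_init__(self) -> None:
        for name in ("vs2_hi", "vs2_lo", "dvf_hi", "dvf_lo",
                     "dvf_p_hi", "dvf_p_lo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("ani_thresh", "af_thresh", "read_min_identity",
                     "read_min_aligned", "min_covered_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown threshold fields: {sorted(unknown)}")
        return cls(**d)


DEFAULT_CONFIG = ThresholdConfig()
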