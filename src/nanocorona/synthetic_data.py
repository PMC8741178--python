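"""Synthetic fixtures with the statistical structure the pipeline assumes.

Generated data emulate three signals the real corpus carries: (i) in-corona
proteins have elevated glycine and depleted leucine content (composition
deltas applied to UniProt-average baseline frequencies); (ii) the
non-enriched portion of the corona-abundance distribution decays
exponentially with a known rate, while an enriched subset exceeds its
biofluid control; (iii) per-residue exposure calls, produced by the
deterministic hydropathy heuristic.  Residues are drawn i.i.d. — there is
no dipeptide structure, so dipeptide-based descriptors behave as noise,
which is acceptable for plumbing and recovery tests.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    AbundanceRecord,
    ProteinRecord,
    STANDARD_AA,
    write_abundance_table,
    write_fasta,
    write_netsurfp,
)
from .solvent_exposure import heuristic_exposure

#: UniProt-wide average amino-acid composition (fractions).
UNIPROT_FREQS = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario."""

    n_per_class: int = 200
    length_range: tuple[int, int] = (80, 300)
    base_freqs: dict[str, float] = field(
        default_factory=lambda: dict(UNIPROT_FREQS)
    )
    composition_deltas: dict[str, float] = field(
        default_factory=lambda: {"G": 2.0, "L": 0.5}
    )
    k_true: float = 0.01
    enriched_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"degenerate length range {self.length_range}")
        if any(f <= 0 for f in self.base_freqs.values()):
            raise ValueError("baseline frequencies must be positive")
        if not 0.0 <= self.enriched_fraction <= 1.0:
            raise ValueError("enriched fraction must be in [0, 1]")
        if self.k_true <= 0:
            raise ValueError("k_true must be positive")


def null_config(seed: int = 0, **kwargs) -> ScenarioConfig:
    """A scenario with no composition signal (zero deltas), so class labels
    are independent of sequence content."""
    return ScenarioConfig(composition_deltas={}, seed=seed, **kwargs)


def _class_freqs(cfg: ScenarioConfig, in_class: bool) -> np.ndarray:
    freqs = np.array([cfg.base_freqs[aa] for aa in STANDARD_AA])
    if in_class:
        for aa, delta in cfg.composition_deltas.items():
            freqs[STANDARD_AA.index(aa)] *= delta
    return freqs / freqs.sum()


def gen_proteins(
    cfg: ScenarioConfig,
) -> tuple[list[ProteinRecord], np.ndarray]:
    """Draw sequences i.i.d. per residue from class-specific frequencies.

    Returns the records (accessions ``SYN0000``…) and the true in-corona
    class labels, deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    letters = np.array(list(STANDARD_AA))
    records: list[ProteinRecord] = []
    labels: list[bool] = []
    idx = 0
    for in_class in (True, False):
        freqs = _class_freqs(cfg, in_class)
        for _ in range(cfg.n_per_class):
            length = int(
                rng.integers(cfg.length_range[0], cfg.length_range[1] + 1)
            )
            seq = "".join(rng.choice(letters, size=length, p=freqs))
            records.append(
                ProteinRecord(accession=f"SYN{idx:04d}", sequence=seq)
            )
            labels.append(in_class)
            idx += 1
    return records, np.array(labels, dtype=bool)


def gen_abundances(
    cfg: ScenarioConfig,
    accessions: Sequence[str],
    enriched: Sequence[bool] | None = None,
) -> tuple[list[AbundanceRecord], float]:
    """Draw abundance records with an exponential non-enriched tail.

    Non-enriched proteins get A_corona ~ Exp(k_true) and a control
    abundance A_biofluid = A_corona × U(1, 3), guaranteeing non-enrichment;
    enriched proteins get A_biofluid ~ Exp(k_true) and
    A_corona = A_biofluid × U(1.5, 5).  The enriched subset is the given
    mask, or a Bernoulli(enriched_fraction) draw when none is supplied.
    Returns the records and the true rate for recovery tests.
    """
    if len(accessions) == 0:
        raise ValueError("accessions must be nonempty")
    rng = np.random.default_rng(cfg.seed + 1)
    if enriched is None:
        enriched_mask = rng.random(len(accessions)) < cfg.enriched_fraction
    else:
        if len(enriched) != len(accessions):
            raise ValueError("enriched mask length mismatch")
        enriched_mask = np.asarray(enriched, dtype=bool)
    scale = 1.0 / cfg.k_true
    records = []
    for acc, is_enr in zip(accessions, enriched_mask):
        if is_enr:
            a_bio = float(rng.exponential(scale))
            a_cor = a_bio * float(rng.uniform(1.5, 5.0))
        else:
            a_cor = float(rng.exponential(scale))
            a_bio = a_cor * float(rng.uniform(1.0, 3.0))
            a_bio = max(a_bio, np.nextafter(a_cor, np.inf))  # never enriched
        records.append(
            AbundanceRecord(accession=acc, a_corona=a_cor, a_biofluid=a_bio)
        )
    return records, cfg.k_true


def gen_scenario(
    cfg: ScenarioConfig, outdir: str | Path, force: bool = False
) -> dict:
    """Write a self-consistent fixture directory.

    Layout: ``proteins.fasta``, ``abundances.csv``, ``exposure.csv``
    (NetSurfP-style, from the heuristic predictor) and ``truth.json``
    (class labels, true rate, seed).  The enriched abundance subset is the
    true in-corona class, so the planted composition signal survives the
    abundance-labeling stage.  Refuses a nonempty target unless *force*.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(
            f"{outdir} exists and is nonempty; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    proteins, labels = gen_proteins(cfg)
    abundances, k_true = gen_abundances(
        cfg, [p.accession for p in proteins], enriched=labels
    )
    exposures = {
        p.accession: heuristic_exposure(p.sequence, seed=cfg.seed + 2)
        for p in proteins
    }
    write_fasta(proteins, outdir / "proteins.fasta")
    write_abundance_table(abundances, outdir / "abundances.csv")
    write_netsurfp(exposures, outdir / "exposure.csv")
    truth = {
        "seed": cfg.seed,
        "k_true": k_true,
        "n_per_class": cfg.n_per_class,
        "composition_deltas": cfg.composition_deltas,
        "labels": {
            p.accession: bool(lab) for p, lab in zip(proteins, labels)
        },
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
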