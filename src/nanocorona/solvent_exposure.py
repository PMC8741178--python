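"""Per-residue solvent accessibility → exposure features.

Exposure enters the feature table under two normalizations: counts of
exposed residues of each amino-acid type divided by either the total number
of (standard) residues or by the number of exposed residues.  The first
says how much of the whole protein is exposed glycine, say; the second says
how much of the *surface* is glycine.

Real runs consume NetSurfP 2.0 output (via :func:`nanocorona.io_formats.
read_netsurfp`).  A deterministic hydropathy-based heuristic predictor is
provided for offline fixtures and tests only — it is not a scientific
substitute for a structure-aware predictor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import ResidueExposure, STANDARD_AA

logger = logging.getLogger(__name__)

# Kyte-Doolittle hydropathy, shared with sequence_features.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Theoretical maximal ASA (Tien et al. set), in Å²; used only by the
# heuristic stand-in predictor to turn an RSA into an ASA.
MAX_ASA_TIEN = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Default exposed/buried RSA cutoff (NetSurfP 2.0's own convention),
#: boundary inclusive.
DEFAULT_RSA_CUTOFF = 0.25


@dataclass
class ExposureFractions:
    """Exposure summary of one protein under both normalizations."""

    exposed_counts: dict[str, int]
    exposed_vs_total: dict[str, float]
    exposed_vs_exposed: dict[str, float]
    mean_rsa: float
    total_asa: float
    exposed_fraction: float


def classify_exposure(
    residues: Sequence[ResidueExposure], rsa_cutoff: float = DEFAULT_RSA_CUTOFF
) -> list[ResidueExposure]:
    """Set each residue's ``exposed`` flag: exposed ⇔ RSA ≥ *rsa_cutoff*."""
    if not 0.0 < rsa_cutoff < 1.0:
        raise ValueError(f"rsa_cutoff must be in (0, 1), got {rsa_cutoff}")
    for res in residues:
        res.exposed = res.rsa >= rsa_cutoff
    return list(residues)


def exposure_fractions(
    sequence: str, residues: Sequence[ResidueExposure]
) -> ExposureFractions:
    """Per-amino-acid exposed fractions under both normalizations.

    Denominators count standard residues only (ambiguous letters are
    carried in the sequence but never counted).  With zero exposed
    residues the exposed-vs-exposed vector is all zeros (logged).
    """
    if len(residues) != len(sequence):
        raise ValueError(
            f"exposure length {len(residues)} != sequence length "
            f"{len(sequence)}"
        )
    standard = [
        (letter, res)
        for letter, res in zip(sequence, residues)
        if letter in STANDARD_AA
    ]
    n_std = len(standard)
    if n_std == 0:
        raise ValueError("sequence contains no standard residues")
    counts = {aa: 0 for aa in STANDARD_AA}
    for letter, res in standard:
        if res.exposed:
            counts[letter] += 1
    n_exposed = sum(counts.values())
    if n_exposed == 0:
        logger.warning("no exposed residues; exposed-vs-exposed set to 0")
    vs_total = {aa: counts[aa] / n_std for aa in STANDARD_AA}
    vs_exposed = {
        aa: (counts[aa] / n_exposed if n_exposed else 0.0)
        for aa in STANDARD_AA
    }
    return ExposureFractions(
        exposed_counts=counts,
        exposed_vs_total=vs_total,
        exposed_vs_exposed=vs_exposed,
        mean_rsa=float(np.mean([r.rsa for _, r in standard])),
        total_asa=float(np.sum([r.asa for _, r in standard])),
        exposed_fraction=n_exposed / n_std,
    )


def heuristic_exposure(
    sequence: str, seed: int | None = None
) -> list[ResidueExposure]:
    """Hydropathy-only exposure stand-in for tests and fixtures.

    Per-residue exposure probability is logistic(−hydropathy): hydrophilic
    residues tend to the surface.  With no seed the call is thresholded at
    0.5 (deterministic); with a seed the exposure flag is Bernoulli-sampled.
    The reported RSA is placed on the exposed/buried side of the default
    0.25 cutoff consistently with the flag, and ASA = RSA × maximal ASA of
    the residue type.  Not a scientific predictor — real runs must ingest
    NetSurfP output.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    out: list[ResidueExposure] = []
    for i, letter in enumerate(sequence, start=1):
        hydropathy = KYTE_DOOLITTLE.get(letter, 0.0)
        prob = 1.0 / (1.0 + math.exp(hydropathy))
        if rng is None:
            exposed = prob > 0.5
        else:
            exposed = bool(rng.random() < prob)
        # RSA consistent with the call at the default inclusive 0.25 cutoff
        rsa = 0.25 + 0.5 * prob if exposed else 0.24 * prob
        asa = rsa * MAX_ASA_TIEN.get(letter, 200.0)
        out.append(
            ResidueExposure(
                position=i, residue=letter, rsa=rsa, asa=asa, exposed=exposed
            )
        )
    return out
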