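"""Sequence-global physicochemical descriptors and min-max scaling.

Every descriptor is computed from the amino-acid sequence alone.  The
default registry carries 75 named features in six groups: the 20 amino-acid
fractions, 8 global descriptors (length, molecular weight, aromaticity,
instability index, GRAVY, isoelectric point, net charge at pH 7, mean
flexibility), 4 secondary-structure propensity fractions, the 20
exposed-vs-total and 20 exposed-vs-exposed amino-acid fractions, and 3
exposure-global summaries (mean RSA, total ASA, exposed-residue fraction).

Conventions: hydropathy is Kyte–Doolittle; instability weights are the
Guruprasad DIWV table; flexibility is the Vihinen normalized-B-factor scale
with a nine-residue center-peaked window; the pKa set is Bjellqvist.
Ambiguous residues (X/B/Z/U/O) are retained in the sequence but excluded
from every numerator and denominator, so all fractions stay normalized over
standard residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils import ProtParamData

from .io_formats import ProteinRecord, ResidueExposure, STANDARD_AA
from .solvent_exposure import (
    KYTE_DOOLITTLE,
    exposure_fractions,
    heuristic_exposure,
)

logger = logging.getLogger(__name__)

#: Secondary-structure propensity sets.  They overlap (L is helix- and
#: sheet-associated, A is sheet-associated), so the four fractions need not
#: sum to 1; "nonstructure" is the fraction of residues in none of the sets.
HELIX_SET = frozenset("VIYFWL")
TURN_SET = frozenset("NPGS")
SHEET_SET = frozenset("EMAL")
STRUCTURE_UNION = HELIX_SET | TURN_SET | SHEET_SET

#: Nine-residue flexibility window, center-peaked, mirrored; normalized by
#: its sum (5.25) so a homopolymer scores exactly its scale value.
FLEX_WEIGHTS = np.array(
    [0.25, 0.4375, 0.625, 0.8125, 1.0, 0.8125, 0.625, 0.4375, 0.25]
)

GLOBAL_FEATURES = (
    "length",
    "molecular_weight",
    "aromaticity",
    "instability_index",
    "gravy",
    "isoelectric_point",
    "charge_at_ph7",
    "mean_flexibility",
)
STRUCTURE_FEATURES = (
    "frac_helix",
    "frac_turn",
    "frac_sheet",
    "frac_nonstructure",
)
EXPOSURE_GLOBAL_FEATURES = ("mean_rsa", "total_asa", "exposed_fraction")

GROUPS = (
    "aa_fraction",
    "global",
    "structure",
    "exposure_vs_total",
    "exposure_vs_exposed",
    "exposure_global",
)


@dataclass(frozen=True)
class DescriptorRegistry:
    """Ordered feature namespace: (name, group) pairs with unique names."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names in registry")
        bad = {g for _, g in self.entries} - set(GROUPS)
        if bad:
            raise ValueError(f"unknown feature groups {sorted(bad)}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def group(self, name: str) -> str:
        for n, g in self.entries:
            if n == name:
                return g
        raise KeyError(name)


def default_registry() -> DescriptorRegistry:
    """The 75-feature default registry (covering the field's named
    descriptors; configurable if a different composition is required)."""
    entries: list[tuple[str, str]] = []
    entries += [(f"frac_aa_{aa}", "aa_fraction") for aa in STANDARD_AA]
    entries += [(name, "global") for name in GLOBAL_FEATURES]
    entries += [(name, "structure") for name in STRUCTURE_FEATURES]
    entries += [
        (f"frac_exposed_vs_total_{aa}", "exposure_vs_total")
        for aa in STANDARD_AA
    ]
    entries += [
        (f"frac_exposed_vs_exposed_{aa}", "exposure_vs_exposed")
        for aa in STANDARD_AA
    ]
    entries += [(name, "exposure_global") for name in EXPOSURE_GLOBAL_FEATURES]
    return DescriptorRegistry(entries=tuple(entries))


#: Feature names carrying the glycine-composition signal; used by the
#: planted-signal analyses.
GLYCINE_FEATURES = (
    "frac_aa_G",
    "frac_exposed_vs_total_G",
    "frac_exposed_vs_exposed_G",
)


@dataclass
class FeatureVector:
    """Named descriptor values for one protein."""

    accession: str
    values: dict[str, float]
    scaled: bool = False
    exposure_source: str = "none"  # netsurfp | heuristic | none


def _standard_only(sequence: str) -> str:
    return "".join(c for c in sequence if c in STANDARD_AA)


def aa_fractions(sequence: str) -> dict[str, float]:
    """Fraction of each standard amino acid among standard residues."""
    std = _standard_only(sequence)
    if not std:
        raise ValueError("sequence contains no standard residues")
    n = len(std)
    return {aa: std.count(aa) / n for aa in STANDARD_AA}


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value."""
    std = _standard_only(sequence)
    if not std:
        raise ValueError("sequence contains no standard residues")
    return ProteinAnalysis(std).gravy()


def mean_flexibility(sequence: str) -> float:
    """Mean of the nine-residue windowed Vihinen flexibility profile.

    All full windows (positions 1..L−8) contribute; for sequences shorter
    than the window the unweighted mean of the per-residue scale is
    returned instead (logged).
    """
    std = _standard_only(sequence)
    if not std:
        raise ValueError("sequence contains no standard residues")
    scale = ProtParamData.Flex
    values = np.array([scale[aa] for aa in std])
    if len(values) < 9:
        logger.info(
            "flexibility window undefined for length %d < 9; using "
            "unweighted per-residue mean", len(values)
        )
        return float(values.mean())
    norm = FLEX_WEIGHTS.sum()
    scores = [
        float(values[i:i + 9] @ FLEX_WEIGHTS) / norm
        for i in range(len(values) - 8)
    ]
    return float(np.mean(scores))


def global_descriptors(sequence: str) -> dict[str, float]:
    """Global physicochemical descriptors of a sequence.

    Molecular weight uses average residue masses minus one water per
    peptide bond; the isoelectric point is found by bisection on the
    Henderson–Hasselbalch net charge (Bjellqvist pKa set) to 0.01 pH.
    """
    std = _standard_only(sequence)
    if not std:
        raise ValueError("sequence contains no standard residues")
    pa = ProteinAnalysis(std)
    return {
        "length": float(len(std)),
        "molecular_weight": pa.molecular_weight(),
        "aromaticity": pa.aromaticity(),
        "instability_index": pa.instability_index(),
        "gravy": pa.gravy(),
        "isoelectric_point": pa.isoelectric_point(),
        "charge_at_ph7": pa.charge_at_pH(7.0),
        "mean_flexibility": mean_flexibility(std),
    }


def ss_fractions(sequence: str) -> dict[str, float]:
    """Secondary-structure propensity-set membership fractions.

    The sets overlap, so helix/turn/sheet need not sum to 1;
    ``frac_nonstructure`` is exactly 1 minus the union fraction.
    """
    std = _standard_only(sequence)
    if not std:
        raise ValueError("sequence contains no standard residues")
    n = len(std)
    return {
        "frac_helix": sum(c in HELIX_SET for c in std) / n,
        "frac_turn": sum(c in TURN_SET for c in std) / n,
        "frac_sheet": sum(c in SHEET_SET for c in std) / n,
        "frac_nonstructure": sum(c not in STRUCTURE_UNION for c in std) / n,
    }


def featurize(
    protein: ProteinRecord,
    exposure: Sequence[ResidueExposure] | None = None,
    registry: DescriptorRegistry | None = None,
    fallback: str = "heuristic",
) -> FeatureVector:
    """Assemble the full unscaled feature vector in registry order.

    With no exposure data the deterministic hydropathy heuristic supplies
    the exposure features (``fallback="heuristic"``, flagged in
    ``exposure_source``); with ``fallback="none"`` the exposure features
    are set to 0 and flagged ``none``.
    """
    registry = registry or default_registry()
    seq = protein.sequence
    source = "netsurfp"
    if exposure is None:
        if fallback == "heuristic":
            exposure = heuristic_exposure(seq)
            source = "heuristic"
        elif fallback == "none":
            source = "none"
        else:
            raise ValueError(f"unknown exposure fallback {fallback!r}")
    elif len(exposure) != len(seq):
        raise ValueError(
            f"{protein.accession}: exposure length {len(exposure)} != "
            f"sequence length {len(seq)}"
        )

    pool: dict[str, float] = {}
    fr = aa_fractions(seq)
    pool.update({f"frac_aa_{aa}": fr[aa] for aa in STANDARD_AA})
    pool.update(global_descriptors(seq))
    pool.update(ss_fractions(seq))
    if exposure is not None:
        ef = exposure_fractions(seq, exposure)
        pool.update(
            {f"frac_exposed_vs_total_{aa}": ef.exposed_vs_total[aa]
             for aa in STANDARD_AA}
        )
        pool.update(
            {f"frac_exposed_vs_exposed_{aa}": ef.exposed_vs_exposed[aa]
             for aa in STANDARD_AA}
        )
        pool["mean_rsa"] = ef.mean_rsa
        pool["total_asa"] = ef.total_asa
        pool["exposed_fraction"] = ef.exposed_fraction
    else:
        for aa in STANDARD_AA:
            pool[f"frac_exposed_vs_total_{aa}"] = 0.0
            pool[f"frac_exposed_vs_exposed_{aa}"] = 0.0
        pool["mean_rsa"] = 0.0
        pool["total_asa"] = 0.0
        pool["exposed_fraction"] = 0.0

    try:
        values = {name: pool[name] for name in registry.names}
    except KeyError as exc:  # registry asks for a feature we cannot compute
        raise KeyError(f"registry feature not computable: {exc}") from exc
    return FeatureVector(
        accession=protein.accession, values=values, exposure_source=source
    )


def feature_table(
    proteins: Sequence[ProteinRecord],
    exposures: Mapping[str, Sequence[ResidueExposure]] | None = None,
    registry: DescriptorRegistry | None = None,
    fallback: str = "heuristic",
) -> pd.DataFrame:
    """Feature vectors for a protein collection as a DataFrame.

    Index is the accession; feature columns follow registry order, plus a
    trailing ``exposure_source`` provenance column.
    """
    registry = registry or default_registry()
    rows = []
    for protein in proteins:
        exp = exposures.get(protein.accession) if exposures else None
        vec = featurize(protein, exp, registry, fallback=fallback)
        row = dict(vec.values)
        row["exposure_source"] = vec.exposure_source
        rows.append(row)
    df = pd.DataFrame(
        rows, index=pd.Index([p.accession for p in proteins], name="accession")
    )
    return df[registry.names + ["exposure_source"]]


@dataclass(frozen=True)
class MinMaxFit:
    """Per-feature min/max learned from a fitting table."""

    mins: pd.Series
    maxs: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.mins.index)


def minmax_fit(table: pd.DataFrame) -> MinMaxFit:
    """Learn per-feature min and max from a table of ≥2 feature vectors."""
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 2:
        raise ValueError("min-max fit requires at least 2 vectors")
    return MinMaxFit(mins=numeric.min(axis=0), maxs=numeric.max(axis=0))


def minmax_apply(fit: MinMaxFit, table: pd.DataFrame) -> pd.DataFrame:
    """Scale features to [0, 1]: (x − min)/(max − min).

    A constant feature maps to 0; values outside the fitted range are
    clipped, so unseen vectors stay in [0, 1].  Unknown feature names
    raise ``ValueError``.
    """
    numeric_cols = [c for c in table.columns if c in fit.feature_names]
    unknown = [
        c for c in table.select_dtypes(include=[np.number]).columns
        if c not in fit.feature_names
    ]
    if unknown:
        raise ValueError(f"features not seen at fit time: {unknown}")
    span = (fit.maxs - fit.mins).replace(0.0, np.inf)  # constant -> 0
    scaled = (table[numeric_cols] - fit.mins[numeric_cols]) / span[numeric_cols]
    return scaled.clip(0.0, 1.0)


def scale_features(table: pd.DataFrame) -> tuple[pd.DataFrame, MinMaxFit]:
    """Fit-and-apply convenience on one table (the default pipeline order
    scales the complete table before any splitting)."""
    fit = minmax_fit(table)
    return minmax_apply(fit, table), fit
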