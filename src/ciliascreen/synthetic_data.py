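"""Synthetic BrainSpan-shaped datasets with known ground truth.

The generator emulates the design of the postnatal developmental
transcriptome cohort the screen targets: ~42 donors aged 4 months to 40
years, each donor sampled (incompletely) across up to 16 brain regions, and
a panel of cilia genes of which a configurable fraction carries a true
linear age trend.  Expression is drawn as

    expr(gene, sample) = intercept + slope * age_donor + N(0, noise_sd)

on the raw RPKM-like scale, truncated at zero (truncations are counted and
logged).  Donor ages are shared across that donor's regions — one brain,
many regions — which reproduces the cross-region correlation structure that
makes region overlaps non-independent.

Ages are drawn uniformly on [0.33, 40] years and snapped to the grid
representable by the ``"N mos"`` / ``"N yrs"`` metadata dialect (whole
months below 2 years, whole years above), so that a written dataset
round-trips exactly through the CSV triplet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    COMPARTMENTS,
    ExpressionMatrix,
    GeneAnnotation,
    REGION_CODES,
    SampleRecord,
    snap_age,
    write_brainspan_triplet,  # re-exported: the writer is the generator's counterpart
)

__all__ = [
    "SimConfig",
    "SimulationError",
    "generate_dataset",
    "make_gene_panel",
    "default_annotations",
    "write_brainspan_triplet",
    "write_ground_truth",
]

log = logging.getLogger(__name__)

AGE_MIN = 0.33
AGE_MAX = 40.0


class SimulationError(ValueError):
    """A simulation configuration cannot produce a usable dataset."""


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset.

    Defaults mirror the target cohort: a 445-gene cilia panel, 42 donors,
    all 16 regions, incomplete donor x region coverage.  ``frac_age_linear``
    is the fraction of (gene, region) pairs carrying a true linear age
    effect; true slope magnitudes of 0.1–5 expression units per year bracket
    the coefficient range a real screen reports on the RPKM scale.
    """

    n_genes: int = 445
    n_donors: int = 42
    regions: tuple[str, ...] = REGION_CODES
    frac_age_linear: float = 0.2
    slope_range: tuple[float, float] = (0.1, 5.0)
    intercept_range: tuple[float, float] = (5.0, 50.0)
    noise_sd: float = 10.0
    missing_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_donors < 1:
            raise SimulationError("n_genes and n_donors must be positive")
        unknown = set(self.regions) - set(REGION_CODES)
        if unknown or not self.regions:
            raise SimulationError(f"invalid regions: {sorted(unknown)}")
        if not 0.0 <= self.frac_age_linear <= 1.0:
            raise SimulationError("frac_age_linear must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationError("missing_rate must lie in [0, 1)")
        for name in ("slope_range", "intercept_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise SimulationError(f"{name} must satisfy 0 <= lo <= hi")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, list[SampleRecord], pd.DataFrame]:
    """Generate one dataset; returns (matrix, samples, ground_truth).

    Ground truth is a long DataFrame with one row per (gene, region):
    columns ``gene``, ``region``, ``true_slope`` (0 for null pairs),
    ``true_intercept``, ``is_age_linear``.  The same config and seed always
    produce byte-identical outputs.

    Raises
    ------
    SimulationError
        If the coverage draw leaves any region with fewer than 3 samples
        (a regression there would be infeasible).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, D, R = config.n_genes, config.n_donors, len(config.regions)

    genes = _gene_symbols(config.n_genes)

    ages = np.array(
        [snap_age(a) for a in rng.uniform(AGE_MIN, AGE_MAX, size=D)]
    )
    n_f = int(round(D * 19 / 42))  # cohort sex balance: 19 F / 23 M of 42
    sexes = rng.permutation(np.array(["F"] * n_f + ["M"] * (D - n_f)))
    donor_ids = [f"D{j:03d}" for j in range(D)]

    observed = rng.random((D, R)) >= config.missing_rate
    per_region = observed.sum(axis=0)
    too_small = [r for r, n in zip(config.regions, per_region) if n < 3]
    if too_small:
        raise SimulationError(
            f"regions with < 3 samples (regression infeasible): {too_small}"
        )

    # Ground truth: choose which (gene, region) pairs carry a true effect.
    n_pairs = G * R
    n_effect = int(round(config.frac_age_linear * n_pairs))
    effect_idx = rng.choice(n_pairs, size=n_effect, replace=False)
    is_linear = np.zeros(n_pairs, dtype=bool)
    is_linear[effect_idx] = True
    slopes = np.zeros(n_pairs)
    lo_s, hi_s = config.slope_range
    magnitudes = rng.uniform(lo_s, hi_s, size=n_effect)
    signs = rng.choice([-1.0, 1.0], size=n_effect)
    slopes[effect_idx] = magnitudes * signs
    lo_b, hi_b = config.intercept_range
    intercepts = rng.uniform(lo_b, hi_b, size=n_pairs)

    slope_gr = slopes.reshape(G, R)
    intercept_gr = intercepts.reshape(G, R)

    samples: list[SampleRecord] = []
    columns: list[np.ndarray] = []
    n_trunc = 0
    sample_no = 0
    for d in range(D):
        for r, region in enumerate(config.regions):
            if not observed[d, r]:
                continue
            sample_no += 1
            sid = f"S{sample_no:04d}"
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    donor_id=donor_ids[d],
                    age_years=float(ages[d]),
                    region=region,
                    sex=str(sexes[d]),
                )
            )
            mean = intercept_gr[:, r] + slope_gr[:, r] * ages[d]
            values = mean + rng.normal(0.0, config.noise_sd, size=G)
            n_trunc += int((values < 0).sum())
            columns.append(np.clip(values, 0.0, None))
    if n_trunc:
        log.info(
            "truncated %d negative expression values to 0 (%.3f%% of matrix)",
            n_trunc, 100.0 * n_trunc / (G * len(samples)),
        )

    data = pd.DataFrame(
        np.column_stack(columns),
        index=pd.Index(genes, name="gene_symbol"),
        columns=[s.sample_id for s in samples],
    )
    ground_truth = pd.DataFrame(
        {
            "gene": np.repeat(genes, R),
            "region": np.tile(config.regions, G),
            "true_slope": slopes,
            "true_intercept": intercepts,
            "is_age_linear": is_linear,
        }
    )
    return ExpressionMatrix(data), samples, ground_truth


def write_ground_truth(ground_truth: pd.DataFrame, path) -> Path:
    """Write the ground-truth table as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ground_truth.to_csv(path, sep="\t", index=False)
    return path


def _gene_symbols(n: int) -> list[str]:
    """First ``n`` panel symbols, padded with GENE#### beyond the panel."""
    panel = [a.symbol for a in make_gene_panel()]
    if n <= len(panel):
        return panel[:n]
    extra = [f"GENE{i:04d}" for i in range(n - len(panel))]
    return panel + extra


def default_annotations(genes: Sequence[str]) -> list[GeneAnnotation]:
    """Compartment annotations for generated gene symbols.

    Panel genes keep their panel compartments; padding symbols fall into
    ``other``.
    """
    lookup = {a.symbol: a for a in make_gene_panel()}
    return [
        lookup.get(g, GeneAnnotation(symbol=g, compartments=frozenset({"other"})))
        for g in genes
    ]


# --- synthetic cilia gene panel ---------------------------------------------

# Per-compartment panel sizes (sum = 445).  Sizes are a plausible
# reconstruction of a curated cilia panel: heavy on basal body, centrosome
# and cytosolic components, with small IFT/BBSome/motor complexes.
_PANEL_SIZES: tuple[tuple[str, int], ...] = (
    ("axoneme", 37),
    ("basal body", 90),
    ("transition zone", 11),
    ("kinesin", 6),
    ("dynein", 10),
    ("IFT-A", 6),
    ("IFT-B", 9),
    ("BBSome", 10),
    ("Golgi", 8),
    ("cytosol", 40),
    ("nucleus", 30),
    ("ciliary membrane", 8),
    ("GPCR", 25),
    ("mitochondria", 12),
    ("centrosome", 40),
    ("other", 103),
)

# Real cilia-associated gene symbols seeding each compartment; the remainder
# of each compartment is filled with clearly synthetic CILSYN### placeholders.
_KNOWN_GENES: dict[str, list[str]] = {
    "axoneme": [
        "TUBA1A", "TUBA1C", "TUBA8", "TUBB", "TUBB2A", "TUBB2B", "TUBB3",
        "TUBB4A", "TUBB4B", "SPAG6", "SPAG16", "SPAG17", "HYDIN", "CFAP43",
        "CFAP44", "CFAP54", "RSPH1", "RSPH4A", "RSPH9", "DNAI1", "DNAI2",
        "PACRG",
    ],
    "basal body": [
        "SNAP25", "TUBG1", "TUBGCP2", "TUBGCP3", "TUBGCP4", "TUBGCP5",
        "TUBGCP6", "CEP164", "CEP290", "CEP83", "CEP89", "OFD1", "SDCCAG8",
        "NPHP1", "MKS1", "B9D1", "B9D2", "TMEM67", "POC1A", "POC1B", "PLK4",
        "SASS6", "STIL", "CEP152", "CEP192", "CENPJ", "ODF2", "NIN", "TTBK2",
        "KIAA0586", "RAB8A", "RAB11A", "EHD1",
    ],
    "transition zone": [
        "NPHP4", "RPGRIP1L", "TMEM216", "TMEM138", "TMEM231", "TMEM237",
        "AHI1", "CC2D2A", "TCTN1", "TCTN2", "TCTN3",
    ],
    "kinesin": ["KIF17", "KIF3A", "KIF3B", "KIF3C", "KIFAP3", "KIF7"],
    "dynein": [
        "DYNC2H1", "DYNC2LI1", "WDR34", "WDR60", "DNAH5", "DNAH11",
        "DNAL1", "DNALI1", "DYNLL1", "DYNLT1",
    ],
    "IFT-A": ["WDR19", "IFT172", "IFT140", "IFT122", "WDR35", "TTC21B"],
    "IFT-B": [
        "IFT88", "IFT80", "IFT20", "IFT27", "IFT52", "IFT57", "IFT74",
        "TTC30A", "TTC30B",
    ],
    "BBSome": [
        "BBS1", "BBS2", "BBS4", "BBS5", "BBS7", "BBS9", "TTC8", "BBIP1",
        "ARL6", "LZTFL1",
    ],
    "Golgi": [
        "TRIP11", "GOLGA2", "GOLGA3", "GORASP1", "GORASP2", "ARF4",
        "RAB6A", "USO1",
    ],
    "cytosol": ["RABL2A", "RABL2B", "TULP3", "UNC119", "UNC119B", "ARL3"],
    "nucleus": ["RFX3", "RFX4", "FOXJ1", "GLI1", "GLI2", "GLI3", "SUFU"],
    "ciliary membrane": [
        "ARL13B", "INPP5E", "PKD1", "PKD2", "PKHD1", "TMEM107", "EVC",
        "EVC2",
    ],
    "GPCR": [
        "MCHR1", "MC4R", "GALR2", "GALR3", "DRD2", "DRD5", "KISS1R", "SMO",
        "SSTR3", "NPY2R", "NPY5R", "LPAR6", "NMUR1", "HTR6", "GPR88",
        "GPR161", "GPR83", "GPR19", "CELSR2", "PTGER4", "OPN4", "TAAR1",
        "ADRB2", "HTR7", "GPR21",
    ],
    "mitochondria": [
        "FIS1", "MFN1", "MFN2", "OPA1", "DNM1L", "TOMM20", "TIMM23",
        "VDAC1",
    ],
    "centrosome": [
        "MAPRE1", "PCNT", "CEP63", "CEP72", "CETN2", "CETN3", "CEP41",
        "CEP97", "CCP110", "CEP76", "CEP135", "CEP250", "NEK2", "PLK1",
    ],
    "other": ["MYO15A", "TRANK1", "TULP2", "FBLN2"],
}

# Genes annotated to two compartments (counted once per compartment in
# roll-ups); CCDC28B sits at the basal body / centrosome interface.
_DUAL_GENES: tuple[tuple[str, frozenset[str]], ...] = (
    ("CCDC28B", frozenset({"basal body", "centrosome"})),
)


def make_gene_panel() -> list[GeneAnnotation]:
    """Deterministically build the synthetic 445-gene cilia panel.

    The panel is a stand-in for a curated cilia gene list: compartment sizes
    and the seeded real gene symbols are plausible, the CILSYN### fillers are
    synthetic.  The shipped ``data/cilia_gene_panel_synthetic.tsv`` is this
    function's output.
    """
    annotations: list[GeneAnnotation] = []
    filler = 1
    dual_by_comp: dict[str, list[tuple[str, frozenset[str]]]] = {}
    for symbol, comps in _DUAL_GENES:
        dual_by_comp.setdefault(sorted(comps)[0], []).append((symbol, comps))

    for compartment, size in _PANEL_SIZES:
        symbols = list(_KNOWN_GENES.get(compartment, []))
        entries: list[GeneAnnotation] = [
            GeneAnnotation(symbol=s, compartments=frozenset({compartment}))
            for s in symbols
        ]
        for symbol, comps in dual_by_comp.get(compartment, []):
            entries.append(GeneAnnotation(symbol=symbol, compartments=comps))
        while len(entries) < size:
            entries.append(
                GeneAnnotation(
                    symbol=f"CILSYN{filler:03d}",
                    compartments=frozenset({compartment}),
                )
            )
            filler += 1
        annotations.extend(entries[:size])
    assert len({a.symbol for a in annotations}) == len(annotations)
    return annotations
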