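"""Synthetic paired-omics generator with planted coexpression structure.

The generator emulates the statistical structure the downstream analysis
assumes: block-modular feature correlation driven by per-module latent
factors, latent factors correlated with the ordinal escalation-of-consumption
(EoC) trait, replicate probe spots with measurement noise and random bad-spot
flags, and planted miRNA-module -> protein repression links producing
anti-correlated cross-omic factors. Matching target-prediction and
protein-protein-interaction tables are generated so the integrative network
stage can be exercised end to end.

Every planted feature carries its module in its name (``mir_m3_7`` is feature
7 of miRNA module 3; ``mir_bg_12`` is background), so ground-truth labels are
recoverable with :func:`planted_labels` without side-channel bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StudyDesign
from .errors import ParameterError, SpecError
from .matrix import ExpressionMatrix

__all__ = [
    "ModuleSpec",
    "RepressionLink",
    "RepressionMap",
    "simulate_expression",
    "simulate_paired_omics",
    "simulate_annotation_tables",
    "planted_labels",
    "default_mirna_modules",
    "default_protein_modules",
    "default_repression_map",
]


@dataclass(frozen=True)
class ModuleSpec:
    """One planted coexpression module.

    ``trait_corr`` is the target population correlation between the module's
    latent factor and the EoC trait; ``loading`` scales how strongly member
    features follow the factor (signal sd relative to the factor's unit sd).
    """

    module_id: int
    size: int
    trait_corr: float = 0.0
    loading: float = 0.8

    def __post_init__(self) -> None:
        if self.size < 1:
            raise SpecError("module size must be >= 1")
        if not -1.0 <= self.trait_corr <= 1.0:
            raise SpecError("|trait_corr| must be <= 1")
        if not 0.0 < self.loading <= 1.0:
            raise SpecError("loading must be in (0, 1]")


@dataclass(frozen=True)
class RepressionLink:
    """Planted miRNA-module -> protein repression.

    The target is either a whole protein module (``protein_module``) or a
    single protein feature (``protein_feature``); exactly one must be given.
    ``strength`` in (0, 1] is the magnitude of the negative correlation
    planted between the miRNA factor and the protein factor/feature signal.
    """

    mirna_module: int
    protein_module: int | None = None
    protein_feature: str | None = None
    strength: float = 1.0

    def __post_init__(self) -> None:
        if (self.protein_module is None) == (self.protein_feature is None):
            raise SpecError("exactly one of protein_module / protein_feature required")
        if not 0.0 < self.strength <= 1.0:
            raise SpecError("repression strength must be in (0, 1]")


@dataclass(frozen=True)
class RepressionMap:
    links: tuple[RepressionLink, ...] = field(default_factory=tuple)

    def __init__(self, links=()):
        object.__setattr__(self, "links", tuple(links))

    def __len__(self) -> int:
        return len(self.links)


def _feature_names(prefix: str, modules: list[ModuleSpec], n_features: int) -> tuple[list[str], pd.Series]:
    """Deterministic feature layout: module members first, then background."""
    total = sum(m.size for m in modules)
    if total > n_features:
        raise SpecError(
            f"module sizes sum to {total}, exceeding the feature budget {n_features}"
        )
    names, labels = [], []
    for m in modules:
        for i in range(m.size):
            names.append(f"{prefix}_m{m.module_id}_{i}")
            labels.append(m.module_id)
    for i in range(n_features - total):
        names.append(f"{prefix}_bg_{i}")
        labels.append(0)
    return names, pd.Series(labels, index=names, name="planted_module")


def planted_labels(feature_ids) -> pd.Series:
    """Recover planted module labels (0 = background) from feature names."""
    out = []
    for fid in feature_ids:
        parts = str(fid).split("_")
        if len(parts) >= 3 and parts[1].startswith("m") and parts[1][1:].isdigit():
            out.append(int(parts[1][1:]))
        else:
            out.append(0)
    return pd.Series(out, index=list(feature_ids), name="planted_module")


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _module_factors(
    design: StudyDesign, modules: list[ModuleSpec], rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Latent factor per module: trait_corr * z(eoc) + sqrt(1-tc^2) * noise.

    Factors are standardized across samples, so the expected correlation with
    the EoC trait equals ``trait_corr`` in the infinite-sample limit.
    """
    z_eoc = _standardize(design.eoc.to_numpy(dtype=float))
    factors = {}
    for m in modules:
        tc = m.trait_corr
        raw = tc * z_eoc + np.sqrt(max(1.0 - tc**2, 0.0)) * rng.normal(size=len(z_eoc))
        factors[m.module_id] = _standardize(raw)
    return factors


def _feature_signals(
    design: StudyDesign,
    modules: list[ModuleSpec],
    factors: dict[int, np.ndarray],
    n_features: int,
    noise_sd: float,
    prefix: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Feature-level log2 signal matrix: loading * factor + N(0, noise_sd)."""
    names, _ = _feature_names(prefix, modules, n_features)
    n = design.n_samples
    values = np.empty((len(names), n))
    row = 0
    for m in modules:
        f = factors[m.module_id]
        for _ in range(m.size):
            values[row] = m.loading * f + rng.normal(0.0, noise_sd, size=n)
            row += 1
    n_bg = len(names) - row
    if n_bg:
        values[row:] = rng.normal(0.0, noise_sd, size=(n_bg, n))
    return pd.DataFrame(values, index=names, columns=design.sample_ids)


def _replicate_spots(
    signals: pd.DataFrame,
    n_replicates: int,
    replicate_noise_sd: float,
    flag_rate: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Expand features to replicate spots sharing the feature signal."""
    spot_ids, feat_of_spot = [], []
    for fid in signals.index:
        for r in range(n_replicates):
            spot_ids.append(f"{fid}::r{r + 1}")
            feat_of_spot.append(fid)
    base = signals.loc[feat_of_spot].to_numpy()
    noise = rng.normal(0.0, replicate_noise_sd, size=base.shape)
    values = pd.DataFrame(base + noise, index=spot_ids, columns=signals.columns)
    flags = pd.DataFrame(
        rng.random(size=base.shape) < flag_rate, index=spot_ids, columns=signals.columns
    )
    rep_map = pd.Series(feat_of_spot, index=spot_ids, name="feature_id")
    return values, flags, rep_map


def simulate_expression(
    design: StudyDesign,
    modules: list[ModuleSpec],
    n_features: int,
    noise_sd: float = 0.6,
    n_replicates: int = 4,
    flag_rate: float = 0.02,
    seed: int = 0,
    replicate_noise_sd: float = 0.3,
    baseline_log2_range: tuple[float, float] = (6.0, 12.0),
    output_scale: str = "intensity",
    prefix: str = "mir",
) -> ExpressionMatrix:
    """Simulate a replicate-spot expression matrix with planted modules.

    Each module's member features follow the module latent factor plus
    feature-level noise; background features are pure noise. Each feature is
    printed as ``n_replicates`` spots that share the feature signal and differ
    only by measurement noise; a fraction ``flag_rate`` of spot x sample
    entries is flagged at random. On the "intensity" scale, per-feature
    baselines uniform on ``baseline_log2_range`` (log2 units) are added and
    values exponentiated, mimicking raw array intensities.
    """
    rng = np.random.default_rng(seed)
    factors = _module_factors(design, modules, rng)
    return _build_matrix(
        design, modules, factors, n_features, noise_sd, n_replicates, flag_rate,
        rng, replicate_noise_sd, baseline_log2_range, output_scale, prefix,
    )


def _build_matrix(
    design: StudyDesign,
    modules: list[ModuleSpec],
    factors: dict[int, np.ndarray],
    n_features: int,
    noise_sd: float,
    n_replicates: int,
    flag_rate: float,
    rng: np.random.Generator,
    replicate_noise_sd: float = 0.3,
    baseline_log2_range: tuple[float, float] = (6.0, 12.0),
    output_scale: str = "intensity",
    prefix: str = "mir",
    signals: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be > 0")
    if not 0.0 <= flag_rate < 1.0:
        raise ParameterError("flag_rate must be in [0, 1)")
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if signals is None:
        signals = _feature_signals(design, modules, factors, n_features, noise_sd, prefix, rng)
    baselines = rng.uniform(*baseline_log2_range, size=len(signals))
    signals = signals.add(baselines, axis=0)
    if n_replicates == 1:
        values, flags, rep_map = signals, None, None
        if flag_rate > 0:
            flags = pd.DataFrame(
                rng.random(size=signals.shape) < flag_rate,
                index=signals.index,
                columns=signals.columns,
            )
    else:
        values, flags, rep_map = _replicate_spots(
            signals, n_replicates, replicate_noise_sd, flag_rate, rng
        )
    if output_scale == "intensity":
        values = np.power(2.0, values)
    elif output_scale != "log2":
        raise ParameterError("output_scale must be 'intensity' or 'log2'")
    return ExpressionMatrix(values=values, scale=output_scale, flags=flags, replicate_map=rep_map)


def _resolve_repression(
    repression: RepressionMap,
    mirna_modules: list[ModuleSpec],
    protein_modules: list[ModuleSpec],
    protein_features: list[str],
) -> None:
    mirna_ids = {m.module_id for m in mirna_modules}
    prot_ids = {m.module_id for m in protein_modules}
    feats = set(protein_features)
    for link in repression.links:
        if link.mirna_module not in mirna_ids:
            raise SpecError(f"repression references unknown miRNA module {link.mirna_module}")
        if link.protein_module is not None and link.protein_module not in prot_ids:
            raise SpecError(f"repression references unknown protein module {link.protein_module}")
        if link.protein_feature is not None and link.protein_feature not in feats:
            raise SpecError(f"repression references unknown protein feature {link.protein_feature}")


def simulate_paired_omics(
    design: StudyDesign,
    mirna_modules: list[ModuleSpec],
    protein_modules: list[ModuleSpec],
    repression: RepressionMap,
    seed: int = 0,
    n_mirna_features: int | None = None,
    n_protein_features: int | None = None,
    noise_sd: float = 0.6,
    n_replicates: int = 4,
    flag_rate: float = 0.02,
    replicate_noise_sd: float = 0.3,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Simulate an miRNA array and a paired protein-abundance matrix.

    For each repression link with strength s, the protein module factor is
    ``-s * f_miRNA + sqrt(1 - s^2) * noise`` (population correlation exactly
    -s with the miRNA factor); unlinked protein modules are independent.
    Feature-level links replace that protein feature's signal the same way.
    The miRNA matrix is produced on the intensity scale with replicate spots
    and flags; the protein matrix mimics standardized log abundances from gel
    spots (log2 scale, single measurement per spot, no flags).
    """
    if n_mirna_features is None:
        n_mirna_features = sum(m.size for m in mirna_modules)
    if n_protein_features is None:
        n_protein_features = sum(m.size for m in protein_modules)
    prot_names, _ = _feature_names("prot", protein_modules, n_protein_features)
    _resolve_repression(repression, mirna_modules, protein_modules, prot_names)

    rng = np.random.default_rng(seed)
    mirna_factors = _module_factors(design, mirna_modules, rng)

    module_links = {l.protein_module: l for l in repression.links if l.protein_module is not None}
    feature_links = {l.protein_feature: l for l in repression.links if l.protein_feature is not None}

    n = design.n_samples
    protein_factors = {}
    for m in protein_modules:
        link = module_links.get(m.module_id)
        if link is None:
            # keep this module's latent draw independent, but respect its own trait_corr
            protein_factors[m.module_id] = _module_factors(design, [m], rng)[m.module_id]
        else:
            s = link.strength
            raw = -s * mirna_factors[link.mirna_module] + np.sqrt(1.0 - s**2) * rng.normal(size=n)
            protein_factors[m.module_id] = _standardize(raw) if raw.std() > 0 else raw

    prot_signals = _feature_signals(
        design, protein_modules, protein_factors, n_protein_features, noise_sd, "prot", rng
    )
    for fid, link in feature_links.items():
        s = link.strength
        raw = -s * mirna_factors[link.mirna_module] + np.sqrt(1.0 - s**2) * rng.normal(size=n)
        sig = _standardize(raw) if raw.std() > 0 else raw
        loading = next(iter(protein_modules)).loading if protein_modules else 0.8
        prot_signals.loc[fid] = loading * sig + rng.normal(0.0, noise_sd, size=n)

    # the miRNA matrix reuses the same module factors the protein factors
    # were derived from, so planted cross-omic correlations are real
    mirna = _build_matrix(
        design,
        mirna_modules,
        mirna_factors,
        n_mirna_features,
        noise_sd,
        n_replicates,
        flag_rate,
        rng,
        replicate_noise_sd=replicate_noise_sd,
        output_scale="intensity",
        prefix="mir",
    )
    protein = ExpressionMatrix(values=prot_signals, scale="log2")
    return mirna, protein


def _representative(prefix: str, module_id: int) -> str:
    return f"{prefix}_m{module_id}_0"


def simulate_annotation_tables(
    repression: RepressionMap,
    mirna_modules: list[ModuleSpec],
    protein_modules: list[ModuleSpec],
    n_decoy_targets: int = 50,
    ppi_density: float = 0.01,
    seed: int = 0,
    n_mirna_features: int | None = None,
    n_protein_features: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate target-prediction and PPI tables consistent with the planting.

    The target table has exactly one row per repression link (representative
    member features stand in for module-level links) marked ``is_planted``,
    plus ``n_decoy_targets`` random decoy pairs. The PPI table contains the
    complete within-module edge set for every protein module plus random
    cross edges at ``ppi_density``, each with a confidence score in [0, 1]
    (planted within-module edges draw from the upper half of the scale).
    """
    if not 0.0 <= ppi_density <= 1.0:
        raise ParameterError("ppi_density must be in [0, 1]")
    if n_mirna_features is None:
        n_mirna_features = sum(m.size for m in mirna_modules)
    if n_protein_features is None:
        n_protein_features = sum(m.size for m in protein_modules)
    mirna_names, _ = _feature_names("mir", mirna_modules, n_mirna_features)
    prot_names, prot_labels = _feature_names("prot", protein_modules, n_protein_features)
    _resolve_repression(repression, mirna_modules, protein_modules, prot_names)
    rng = np.random.default_rng(seed)

    rows = []
    for link in repression.links:
        gene = (
            link.protein_feature
            if link.protein_feature is not None
            else _representative("prot", link.protein_module)
        )
        rows.append(
            {
                "mirna_id": _representative("mir", link.mirna_module),
                "gene_id": gene,
                "evidence": "observed",
                "source": "planted",
                "is_planted": True,
            }
        )
    seen = {(r["mirna_id"], r["gene_id"]) for r in rows}
    while len(rows) < len(repression.links) + n_decoy_targets:
        pair = (
            mirna_names[rng.integers(len(mirna_names))],
            prot_names[rng.integers(len(prot_names))],
        )
        if pair in seen:
            continue
        seen.add(pair)
        rows.append(
            {
                "mirna_id": pair[0],
                "gene_id": pair[1],
                "evidence": "observed" if rng.random() < 0.5 else "predicted",
                "source": "decoy",
                "is_planted": False,
            }
        )
    targets = pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "evidence", "source", "is_planted"]
    )

    ppi_rows = []
    within = set()
    for m in protein_modules:
        members = [n for n in prot_names if prot_labels[n] == m.module_id]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = sorted((members[i], members[j]))
                within.add((a, b))
                ppi_rows.append(
                    {
                        "gene_a": a,
                        "gene_b": b,
                        "confidence": rng.uniform(0.4, 1.0),
                        "is_planted": True,
                    }
                )
    n_prot = len(prot_names)
    n_pairs = n_prot * (n_prot - 1) // 2
    n_decoy_edges = rng.binomial(max(n_pairs - len(within), 0), ppi_density)
    added = 0
    while added < n_decoy_edges:
        i, j = rng.integers(n_prot, size=2)
        if i == j:
            continue
        a, b = sorted((prot_names[i], prot_names[j]))
        if (a, b) in within:
            continue
        within.add((a, b))
        ppi_rows.append(
            {"gene_a": a, "gene_b": b, "confidence": rng.uniform(0.0, 1.0), "is_planted": False}
        )
        added += 1
    ppi = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "confidence", "is_planted"])
    return targets, ppi


def default_mirna_modules(
    n_modules: int = 8, module_size: int = 25, loading: float = 0.8
) -> list[ModuleSpec]:
    """Default planted miRNA modules: 8 modules of 25 features.

    Trait correlations alternate in sign with magnitudes in the 0.6-0.7 range
    observed for the strongest module-trait correlations in this kind of
    study; two modules are trait-neutral.
    """
    corrs = [0.7, -0.65, 0.6, -0.6, 0.65, -0.7, 0.0, 0.0]
    return [
        ModuleSpec(module_id=i + 1, size=module_size, trait_corr=corrs[i % len(corrs)], loading=loading)
        for i in range(n_modules)
    ]


def default_protein_modules(
    n_modules: int = 6, module_size: int = 20, loading: float = 0.8
) -> list[ModuleSpec]:
    corrs = [0.65, -0.6, 0.6, 0.0, -0.65, 0.0]
    return [
        ModuleSpec(module_id=i + 1, size=module_size, trait_corr=corrs[i % len(corrs)], loading=loading)
        for i in range(n_modules)
    ]


def default_repression_map() -> RepressionMap:
    """Two planted module-level repression links between EoC-relevant modules."""
    return RepressionMap(
        [
            RepressionLink(mirna_module=1, protein_module=2, strength=0.9),
            RepressionLink(mirna_module=3, protein_module=5, strength=0.8),
        ]
    )
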