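"""Bidirectional cross-omic module-trait integration.

The cross-omic step correlates module eigengenes of one omic (e.g. miRNA
coexpression modules) against the ordinal escalation-of-consumption (EoC)
trait, the drinking amounts, and individual feature traces of the *other*
omic (e.g. single protein abundances), and vice versa. Module pairs whose
eigengenes are negatively correlated while both relate strongly to the EoC
trait are candidate repression relationships (miRNA up / protein down along
the escalation axis).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .coexpression import EigengeneMatrix, correlation_with_p
from .design import StudyDesign
from .errors import AlignmentError, InvalidDesignError
from .matrix import ExpressionMatrix


def encode_eoc(design: StudyDesign) -> pd.Series:
    """Ordinal EoC codes per sample: 0 naive, 1 Air-2BC, 2 CIE-2BC."""
    mapping = {"Naive": 0, "Air2BC": 1, "CIE2BC": 2}
    groups = design.groups
    unknown = set(groups) - set(mapping)
    if unknown:
        raise InvalidDesignError(f"unknown group labels: {sorted(unknown)}")
    return groups.map(mapping).astype(float).rename("eoc")


def trait_frame(design: StudyDesign) -> pd.DataFrame:
    """Sample x trait frame with the EoC code and drinking amounts."""
    return pd.DataFrame({"eoc": encode_eoc(design), "drinking": design.drinking})


def select_trait_features(
    gs: pd.DataFrame, p_max: float = 0.05, r_min: float = 0.5, top_k: int = 20
) -> list[str]:
    """Pick trait-worthy features: p <= p_max, |GS| >= r_min, top_k by |GS|.

    These are the features of one omic used as traits for the other omic's
    modules. Returns an empty list (with a warning) when nothing qualifies.
    """
    ok = gs[(gs["p"] <= p_max) & (gs["GS"].abs() >= r_min)]
    if ok.empty:
        warnings.warn("no features pass the trait-selection thresholds")
        return []
    ok = ok.sort_values("GS", key=np.abs, ascending=False, kind="stable")
    return list(ok["feature_id"].head(top_k))


def cross_omic_table(
    eigengenes: EigengeneMatrix,
    traits: pd.DataFrame,
    eoc: pd.Series | None = None,
) -> pd.DataFrame:
    """Correlate each module eigengene with each trait column.

    ``traits`` mixes sample covariates (EoC, drinking) and feature traces of
    the other omic. When ``eoc`` is given, each row gets a direction
    concordance flag: sign(r_module,trait) * sign(r_module,EoC), so -1 marks
    traits moving against an EoC-relevant module.
    """
    traits = traits.reindex(eigengenes.sample_ids)
    if traits.isna().any().any():
        raise AlignmentError("trait samples do not align with eigengene samples")
    if eoc is not None:
        eoc = eoc.reindex(eigengenes.sample_ids)
        if eoc.isna().any():
            raise AlignmentError("EoC samples do not align with eigengene samples")
    rows = []
    for module in eigengenes.values.index:
        me = eigengenes.values.loc[module]
        r_eoc = correlation_with_p(me, eoc)[0] if eoc is not None else np.nan
        for trait in traits.columns:
            r, p = correlation_with_p(me, traits[trait])
            row = {"module": module, "trait": trait, "r": r, "p": p}
            if eoc is not None:
                row["concordance_vs_eoc"] = int(np.sign(r) * np.sign(r_eoc)) if r != 0 else 0
            rows.append(row)
    return pd.DataFrame(rows)


def anti_correlation_report(
    me_mirna: EigengeneMatrix,
    me_protein: EigengeneMatrix,
    eoc: pd.Series,
    r_screen: float = 0.5,
    mirna_expr: ExpressionMatrix | None = None,
    protein_expr: ExpressionMatrix | None = None,
    partition_protein=None,
    n_support: int = 3,
) -> pd.DataFrame:
    """Rank anti-correlated miRNA-module / protein-module pairs.

    Pairs with cor(ME_miRNA, ME_protein) < 0 and |cross-correlation| >=
    ``r_screen`` are ranked by |r(ME_miRNA, EoC)| + |r(ME_protein, EoC)|,
    the combined trait relevance of the two modules. If the protein
    expression matrix and partition are supplied, each pair also reports the
    ``n_support`` protein members most negatively correlated with the miRNA
    eigengene as feature-level supporting evidence.
    """
    if me_mirna.sample_ids != me_protein.sample_ids:
        raise AlignmentError("eigengene matrices are not sample-aligned")
    eoc = eoc.reindex(me_mirna.sample_ids)
    if eoc.isna().any():
        raise AlignmentError("EoC samples do not align with eigengene samples")
    rows = []
    for ma in me_mirna.values.index:
        a = me_mirna.values.loc[ma]
        r_a = correlation_with_p(a, eoc)[0]
        for mb in me_protein.values.index:
            b = me_protein.values.loc[mb]
            r_ab, p_ab = correlation_with_p(a, b)
            if r_ab >= 0 or abs(r_ab) < r_screen:
                continue
            r_b = correlation_with_p(b, eoc)[0]
            row = {
                "mirna_module": ma,
                "protein_module": mb,
                "r_cross": r_ab,
                "p_cross": p_ab,
                "r_mirna_eoc": r_a,
                "r_protein_eoc": r_b,
                "trait_relevance": abs(r_a) + abs(r_b),
            }
            if protein_expr is not None and partition_protein is not None:
                mod_id = int(str(mb).removeprefix("ME"))
                members = partition_protein.members(mod_id)
                support = []
                for fid in members:
                    r_f = correlation_with_p(a, protein_expr.values.loc[fid])[0]
                    support.append((r_f, fid))
                support.sort()
                row["supporting_features"] = ";".join(
                    f"{fid}:{r_f:.3f}" for r_f, fid in support[:n_support]
                )
            rows.append(row)
    cols = [
        "mirna_module", "protein_module", "r_cross", "p_cross",
        "r_mirna_eoc", "r_protein_eoc", "trait_relevance",
    ]
    if rows and "supporting_features" in rows[0]:
        cols.append("supporting_features")
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("trait_relevance", ascending=False, kind="stable").reset_index(drop=True)
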