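"""End-to-end orchestration: preprocessing -> model fits -> FDR thresholds.

Keeps the per-level processing order in one place:

* RNA: log -> quantile normalise -> (joint complete-case) -> TRV filter
  (threshold 3) -> LOWESS.
* protein: intensity-sum normalise (top 5% excluded) -> log -> (joint
  complete-case) -> TRV filter (threshold 2) -> LOWESS.

The complete-case and TRV filters are applied jointly: the final gene set
is the intersection of genes passing in every matrix (both levels, both
replicates), mirroring a "complete high-confidence dataset" design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import preprocess as pp
from .containers import PROTEIN, RNA, ExpressionMatrix, PecaFit
from .peca_model import PecaConfig, compute_residuals, fdr_threshold, fit_peca


@dataclass
class PreprocessResult:
    rna: list[ExpressionMatrix]
    protein: list[ExpressionMatrix]
    reports: dict[str, pd.DataFrame] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)


def preprocess_dataset(
    rna: list[ExpressionMatrix],
    protein: list[ExpressionMatrix],
    trv_rna: float = pp.TRV_THRESHOLD_RNA,
    trv_protein: float = pp.TRV_THRESHOLD_PROTEIN,
    smooth: bool = True,
) -> PreprocessResult:
    """Normalise, filter and smooth all matrices of a paired dataset."""
    rna_n = [pp.quantile_normalize(pp.log_transform(m)) for m in rna]
    prot_n = [pp.log_transform(pp.lfq_sum_normalize(m)) for m in protein]
    genes = pp.complete_case_filter(rna_n + prot_n)
    rna_n = [m.copy_with(m.values.loc[genes]) for m in rna_n]
    prot_n = [m.copy_with(m.values.loc[genes]) for m in prot_n]

    reports: dict[str, pd.DataFrame] = {}
    retained = pd.Index(genes)
    filtered = []
    for m, thr in [(m, trv_rna) for m in rna_n] + [(m, trv_protein) for m in prot_n]:
        fm, report = pp.trv_filter(m, thr)
        reports[f"{m.level}_r{m.replicate}"] = report
        retained = retained.intersection(fm.gene_ids)
        filtered.append(fm)
    rna_f = [m.copy_with(m.values.loc[retained]) for m in filtered[: len(rna_n)]]
    prot_f = [m.copy_with(m.values.loc[retained]) for m in filtered[len(rna_n):]]

    if smooth:
        rna_f = [pp.lowess_smooth_matrix(m) for m in rna_f]
        prot_f = [pp.lowess_smooth_matrix(m) for m in prot_f]
    return PreprocessResult(rna=rna_f, protein=prot_f, reports=reports, genes=list(retained))


@dataclass
class LevelResult:
    """Fits, pooled FDR threshold and attained estFDR for one level."""

    fits: list[PecaFit]
    thresholds: list[float | None]


def run_peca(
    rna: list[ExpressionMatrix],
    protein: list[ExpressionMatrix],
    config: PecaConfig | None = None,
    target_fdr: float = 0.05,
) -> dict[str, LevelResult]:
    """Fit the model per level and replicate; replicates are never pooled.

    RNA-level analysis uses the constant precursor; protein-level analysis
    uses the matched RNA replicate as precursor.  The FDR threshold is
    computed per level and replicate from that fit's pooled scores.
    """
    out: dict[str, LevelResult] = {}
    rna_fits = [fit_peca(compute_residuals(m), config) for m in rna]
    prot_fits = [
        fit_peca(compute_residuals(p, precursor=r), config) for p, r in zip(protein, rna)
    ]
    for level, fits in ((RNA, rna_fits), (PROTEIN, prot_fits)):
        thresholds = [fdr_threshold(f.cps, target_fdr) for f in fits]
        out[level] = LevelResult(fits=fits, thresholds=thresholds)
    return out
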