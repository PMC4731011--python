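"""Phase-level summaries, discordance/buffering detection, divergence curves.

The stress-response time course splits into three phases — early (< 2 h),
intermediate (2-8 h), late (> 8 h).  Per gene, level and phase we take the
maximum change-point score over the phase's interior time points and call
the phase significant when that maximum clears the level's FDR threshold.
Cross-tabulating RNA vs protein phase calls by direction gives the
contingency tables; genes whose RNA and protein rate-ratio trajectories
anticorrelate in both replicates (with at least one significant event at
each level) are *discordant*, and the discordant genes whose protein
concentration stays within a 1.5-fold span in both replicates are
*buffered* — RNA changes counterbalanced into a flat protein output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LOG, ConfigurationError, ExpressionMatrix, PecaFit

DIRECTIONS = ("up", "none", "down")


@dataclass
class PhaseDefinition:
    """Mapping of interior time points (hours) to response phases."""

    phases: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "early": (0.5, 1.0),
            "intermediate": (2.0, 8.0),
            "late": (16.0, 24.0),
        }
    )

    def validate(self, interior: np.ndarray) -> None:
        assigned = [t for pts in self.phases.values() for t in pts]
        if sorted(assigned) != sorted(float(t) for t in interior):
            raise ConfigurationError("phases must cover every interior point exactly once")
        for name, pts in self.phases.items():
            if not pts:
                raise ConfigurationError(f"phase {name!r} has no interior points")


def phase_calls(
    fit: PecaFit,
    threshold,
    phases: PhaseDefinition | None = None,
    level: str = "",
) -> pd.DataFrame:
    """Per gene x phase: max CPS, significance, direction at the argmax.

    Ties in CPS within a phase resolve toward the earlier time point.  With
    a no-signal threshold (None) nothing is significant.
    """
    phases = phases or PhaseDefinition()
    interior = np.asarray(fit.cps.columns, dtype=float)
    phases.validate(interior)
    rows = []
    for phase, pts in phases.phases.items():
        pts = sorted(float(t) for t in pts)
        sub = fit.cps[pts]
        # first occurrence of the max along sorted columns = earlier-time tie rule
        argmax_pos = sub.to_numpy().argmax(axis=1)
        max_cps = sub.to_numpy()[np.arange(len(sub)), argmax_pos]
        for i, gene in enumerate(sub.index):
            t_star = pts[argmax_pos[i]]
            sig = threshold is not None and max_cps[i] >= threshold
            d = fit.direction.loc[gene, t_star]
            rows.append(
                {
                    "gene_id": gene,
                    "level": level,
                    "phase": phase,
                    "max_cps": float(max_cps[i]),
                    "time": t_star,
                    "significant": bool(sig),
                    "direction": ("up" if d > 0 else "down" if d < 0 else "none") if sig else "none",
                }
            )
    return pd.DataFrame(rows)


def contingency_table(
    rna_calls: pd.DataFrame, protein_calls: pd.DataFrame, phase: str
) -> pd.DataFrame:
    """3x3 joint direction counts (RNA up/none/down x protein up/none/down)."""
    r = rna_calls[rna_calls["phase"] == phase].set_index("gene_id")["direction"]
    p = protein_calls[protein_calls["phase"] == phase].set_index("gene_id")["direction"]
    shared = r.index.intersection(p.index)
    only = r.index.symmetric_difference(p.index)
    if len(only):
        warnings.warn(f"{len(only)} genes present at one level only; excluded", stacklevel=2)
    table = pd.DataFrame(0, index=list(DIRECTIONS), columns=list(DIRECTIONS))
    table.index.name = "rna"
    table.columns.name = "protein"
    for gene in shared:
        table.loc[r[gene], p[gene]] += 1
    return table


def _has_significant_event(calls: pd.DataFrame, gene: str) -> bool:
    sub = calls[calls["gene_id"] == gene]
    return bool(sub["significant"].any())


def discordant_genes(
    rna_fits: list[PecaFit],
    protein_fits: list[PecaFit],
    rna_calls: pd.DataFrame,
    protein_calls: pd.DataFrame,
) -> list[str]:
    """Genes with anticorrelated RNA/protein rate-ratio trajectories.

    Requires Pearson correlation between the RNA and protein per-interval
    posterior-mean rate ratios strictly below zero in *both* replicates,
    plus at least one significant event at each level (in any replicate,
    taken from the pooled phase calls).  Genes whose trajectory variance
    vanishes in any replicate are excluded (correlation undefined).
    """
    if len(rna_fits) != len(protein_fits):
        raise ConfigurationError("need matching replicate fits for both levels")
    genes = rna_fits[0].theta_mean.index
    for f in rna_fits + protein_fits:
        genes = genes.intersection(f.theta_mean.index)
    out = []
    for gene in genes:
        ok = True
        for fr, fp in zip(rna_fits, protein_fits):
            a = fr.theta_mean.loc[gene].to_numpy(dtype=float)
            b = fp.theta_mean.loc[gene].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                ok = False
                break
            r, _ = stats.pearsonr(a, b)
            if not (r < 0):
                ok = False
                break
        if not ok:
            continue
        if _has_significant_event(rna_calls, gene) and _has_significant_event(protein_calls, gene):
            out.append(gene)
    return out


def buffered_genes(
    discordant: list[str],
    protein_matrices: list[ExpressionMatrix],
    fold_cut: float = 1.5,
) -> list[str]:
    """Discordant genes whose protein span stays below ``fold_cut``.

    The span is max/min over the time course on the natural scale (the
    strictest reading of "changes smaller than 1.5-fold"), required in
    every supplied replicate.
    """
    out = []
    for gene in discordant:
        keep = True
        for m in protein_matrices:
            if gene not in m.values.index:
                keep = False
                break
            vals = m.values.loc[gene].to_numpy(dtype=float)
            if m.scale == LOG:
                span = float(np.exp(np.nanmax(vals) - np.nanmin(vals)))
            else:
                span = float(np.nanmax(vals) / np.nanmin(vals))
            if not span < fold_cut:
                keep = False
                break
        if keep:
            out.append(gene)
    return out


def divergence_curves(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per time point: R^2 against time 0 and fold-change summaries.

    Returns columns ``r2`` (squared Pearson correlation of the gene vector
    at t vs at t0), ``mean_abs_log10_fc`` (mean over genes of
    \\|log10 fold change vs t0\\|) and ``sd_log10_fc``.  A zero-variance
    column yields NaN for R^2.
    """
    if matrix.scale != LOG:
        raise ConfigurationError("divergence curves expect a log-scale matrix")
    vals = matrix.values.to_numpy(dtype=float)
    t0 = vals[:, 0]
    rows = []
    for j, t in enumerate(matrix.time_grid):
        col = vals[:, j]
        if np.ptp(col) == 0 or np.ptp(t0) == 0:
            r2 = np.nan
        else:
            r, _ = stats.pearsonr(t0, col)
            r2 = float(r * r)
        log10_fc = (col - t0) / np.log(10.0)
        rows.append(
            {
                "time": float(t),
                "r2": r2,
                "mean_abs_log10_fc": float(np.mean(np.abs(log10_fc))),
                "sd_log10_fc": float(np.std(log10_fc, ddof=1)) if len(log10_fc) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("time")
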