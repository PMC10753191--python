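"""Cq-based myosin-isoform expression summaries.

Relative quantities assume an amplification efficiency of exactly 2 per cycle
(no dilution-series efficiencies are fitted), normalised to the arithmetic
mean Cq of the three reference genes HPRT1, RPL13A and SDHA (equivalent to the
geometric mean of their back-transformed quantities, geNorm-style):

    RQ = 2**-(Cq_target - mean(Cq_refs)),  reported as log10(RQ).

Within-sample isoform proportions are estimated directly from raw Cq values,

    p_i = 2**-Cq_i / sum_j 2**-Cq_j,

over either all six myosin heavy chain genes or the four non-regenerative ones
(excluding the embryonic and neonatal isoforms).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_core import ValidationError

REFERENCE_GENES = ("HPRT1", "RPL13A", "SDHA")
MHC_GENES = ("MYH7", "MYH2", "MYH1", "MYH4", "MYH3", "MYH8")
#: isoform protein names keyed by gene
MHC_ISOFORMS = {"MYH7": "MHC1b", "MYH2": "MHC2A", "MYH1": "MHC2X",
                "MYH4": "MHC2B", "MYH3": "MHCemb", "MYH8": "MHCneo"}
REGENERATIVE_GENES = ("MYH3", "MYH8")
NON_REGENERATIVE_GENES = tuple(g for g in MHC_GENES if g not in REGENERATIVE_GENES)


def collapse_replicates(table: pd.DataFrame, sd_flag: float = 0.5) -> pd.DataFrame:
    """Arithmetic-mean Cq per (sample, gene); flag replicate sd > ``sd_flag`` cycles.

    Returns columns sample_id, genotype, gene, Cq, n_replicates, flagged.
    """
    grouped = table.groupby(["sample_id", "genotype", "gene"], as_index=False).agg(
        Cq=("Cq", "mean"),
        n_replicates=("Cq", "size"),
        replicate_sd=("Cq", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
    )
    grouped["flagged"] = grouped["replicate_sd"] > sd_flag
    return grouped


def relative_quantity(collapsed: pd.DataFrame, sample_id: str, target: str) -> float:
    """log10 relative quantity of ``target`` in ``sample_id`` vs the reference genes."""
    sample = collapsed[collapsed["sample_id"] == sample_id]
    refs = sample[sample["gene"].isin(REFERENCE_GENES)]
    if set(refs["gene"]) != set(REFERENCE_GENES):
        missing = set(REFERENCE_GENES) - set(refs["gene"])
        raise ValidationError(f"sample {sample_id!r} missing reference gene(s) {sorted(missing)}")
    row = sample[sample["gene"] == target]
    if row.empty:
        raise ValidationError(f"sample {sample_id!r} has no Cq for {target!r}")
    delta = float(row["Cq"].iloc[0]) - float(refs["Cq"].mean())
    return float(-delta * np.log10(2.0))


def isoform_proportions(collapsed: pd.DataFrame, sample_id: str,
                        gene_scope=MHC_GENES) -> dict[str, float]:
    """Within-sample transcript proportions p_i = 2^-Cq_i / sum_j 2^-Cq_j."""
    scope = tuple(gene_scope)
    if not scope:
        raise ValidationError("empty gene scope")
    sample = collapsed[(collapsed["sample_id"] == sample_id)
                       & (collapsed["gene"].isin(scope))]
    present = sample.set_index("gene")["Cq"]
    if len(present) < 2:
        raise ValidationError(
            f"sample {sample_id!r} has {len(present)} gene(s) in scope; need >= 2")
    cq = present.reindex([g for g in scope if g in present.index]).to_numpy(float)
    # subtract the minimum before exponentiating for numerical stability;
    # proportions are invariant to adding a constant to every Cq in scope
    q = np.exp2(-(cq - cq.min()))
    p = q / q.sum()
    return {g: float(v) for g, v in zip(present.reindex(
        [g for g in scope if g in present.index]).index, p)}


def expression_summary(table: pd.DataFrame, sd_flag: float = 0.5) -> pd.DataFrame:
    """Per-sample log10 RQ and isoform proportions for every myosin gene.

    Produces one row per (sample, gene in the myosin panel) with columns
    log10_rq, proportion_all, proportion_non_regen (NaN for regenerative
    isoforms in the reduced scope).
    """
    collapsed = collapse_replicates(table, sd_flag=sd_flag)
    rows = []
    for sample_id, sub in collapsed.groupby("sample_id"):
        genotype = sub["genotype"].iloc[0]
        genes = [g for g in MHC_GENES if g in set(sub["gene"])]
        p_all = isoform_proportions(collapsed, sample_id, genes)
        non_regen = [g for g in genes if g not in REGENERATIVE_GENES]
        p_nr = isoform_proportions(collapsed, sample_id, non_regen) \
            if len(non_regen) >= 2 else {}
        for gene in genes:
            rows.append(dict(
                sample_id=sample_id, genotype=genotype, gene=gene,
                isoform=MHC_ISOFORMS.get(gene, gene),
                log10_rq=relative_quantity(collapsed, sample_id, gene),
                proportion_all=p_all.get(gene, float("nan")),
                proportion_non_regen=p_nr.get(gene, float("nan")),
            ))
    return pd.DataFrame(rows)
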