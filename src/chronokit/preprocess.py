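"""Readcount preprocessing: RPM normalization, log fold change, outgrowth removal.

Log fold changes are computed as ``log2(RPM + 1)`` of a late time point minus
``log2(RPM + 1)`` of its pDNA batch, with multiple pDNA measurements of the
same batch summed *before* RPM normalization.  The +1 pseudocount is applied
after scaling to reads per million.

Clonal outgrowths — single (replicate, sgRNA) entries whose counts are driven
by a fitness mutation or other artifact unrelated to the intended knockout —
are detected as entries whose LFC both exceeds ``lfc_threshold`` and exceeds
the next-highest LFC among sibling guides of the same gene by more than
``gap_threshold``; detected entries are masked (set NaN) in the raw counts so
every downstream consumer sees the mask.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .screen_data import GeneEffectMatrix, ScreenData

logger = logging.getLogger("chronokit")

DEFAULT_LFC_THRESHOLD = 2.0
DEFAULT_GAP_THRESHOLD = 2.0


def normalize_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to reads per million over its unmasked entries.

    NaN entries are excluded from the denominator and preserved.  Rows whose
    unmasked entries are all zero (or all NaN) cannot be normalized and raise
    a ``ValueError`` naming the sequence.
    """
    values = counts.to_numpy(dtype=float)
    row_sums = np.nansum(values, axis=1)
    all_nan = np.all(np.isnan(values), axis=1)
    bad = (row_sums <= 0) | all_nan
    if bad.any():
        raise ValueError(
            f"cannot RPM-normalize zero/all-NaN sequences: {counts.index[bad][:5].tolist()}"
        )
    return counts.div(row_sums, axis=0) * 1e6


def sum_pdna_batches(data: ScreenData) -> ScreenData:
    """Collapse multiple pDNA measurements of a batch into one summed row.

    Sums are elementwise over raw counts (before RPM).  NaN entries within a
    pDNA row are treated as 0 in the sum and logged.  Batches with a single
    pDNA row pass through unchanged (up to the reserved row name).
    """
    pdna = data.pdna_map
    late = data.replicate_map
    summed_rows = {}
    new_map_rows = []
    for batch, grp in pdna.groupby("pDNA_batch", sort=True):
        rows = data.counts.loc[grp["sequence_ID"]]
        n_nan = int(rows.isna().to_numpy().sum())
        if n_nan:
            logger.warning(
                "pDNA batch %r has %d NaN count entries; treated as 0 in the batch sum",
                batch,
                n_nan,
            )
        name = f"pDNA_{batch}"
        summed_rows[name] = rows.sum(axis=0, skipna=True)
        new_map_rows.append(
            {
                "sequence_ID": name,
                "cell_line_name": "pDNA",
                "pDNA_batch": batch,
                "days": 0.0,
                "library": grp["library"].iloc[0],
            }
        )
    counts = pd.concat(
        [pd.DataFrame(summed_rows).T, data.counts.loc[late["sequence_ID"]]]
    )
    sequence_map = pd.concat(
        [pd.DataFrame(new_map_rows), late], ignore_index=True
    )
    return ScreenData(counts=counts, sequence_map=sequence_map, guide_map=data.guide_map)


def compute_lfc(data: ScreenData) -> pd.DataFrame:
    """Log2 fold change of each late replicate against its pDNA batch.

    ``lfc[k, j] = log2(RPM_kj + 1) - log2(RPM_pdna(b(k)), j + 1)`` where pDNA
    measurements of a batch have been summed before RPM normalization.  Both
    steps are applied internally and are idempotent, so raw or already
    batch-summed inputs give the same result.
    """
    collapsed = sum_pdna_batches(data)
    rpm = normalize_rpm(collapsed.counts)
    log_rpm = np.log2(rpm + 1.0)
    late = collapsed.replicate_map
    pdna_rows = collapsed.pdna_map.set_index("pDNA_batch")["sequence_ID"]
    missing = set(late["pDNA_batch"]) - set(pdna_rows.index)
    if missing:
        raise ValueError(f"no pDNA measurement for batches {sorted(missing)[:5]}")
    baseline = log_rpm.loc[pdna_rows.loc[late["pDNA_batch"]].to_numpy()]
    baseline.index = late["sequence_ID"].to_numpy()
    lfc = log_rpm.loc[late["sequence_ID"]] - baseline
    return lfc


def naive_gene_effect(
    lfc: pd.DataFrame, guide_map: pd.DataFrame, sequence_map: pd.DataFrame
) -> GeneEffectMatrix:
    """Median-of-medians gene score: per-replicate median over a gene's sgRNA
    LFCs, then per-line median over replicates."""
    genes = guide_map.set_index("sgrna")["gene"].reindex(lfc.columns)
    per_replicate = lfc.T.groupby(genes).median().T
    lines = sequence_map.set_index("sequence_ID")["cell_line_name"].reindex(
        per_replicate.index
    )
    per_line = per_replicate.groupby(lines).median()
    per_line.index.name = "cell_line_name"
    empty = per_line.columns[per_line.isna().all(axis=0)]
    if len(empty):
        logger.warning(
            "genes with all-NaN sgRNA LFCs scored NaN: %s", empty[:5].tolist()
        )
    return GeneEffectMatrix(data=per_line, normalization="raw")


def remove_clonal_outgrowths(
    data: ScreenData,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> tuple[ScreenData, pd.DataFrame]:
    """Mask suspected clonal outgrowths in the raw counts.

    An entry is masked when its LFC exceeds ``lfc_threshold`` (log2 units)
    *and* exceeds the next-highest LFC among guides of the same gene in that
    replicate by more than ``gap_threshold``.  Genes with a single guide have
    no defined gap and are never masked.  Returns the masked copy of the data
    and a report table (sequence_ID, sgrna, gene, lfc, gap).
    """
    if lfc_threshold <= 0 or gap_threshold <= 0:
        raise ValueError("outgrowth thresholds must be positive")
    lfc = compute_lfc(data)
    genes = data.guide_genes().reindex(lfc.columns)
    values = lfc.to_numpy()
    filled = np.where(np.isnan(values), -np.inf, values)

    n_single = 0
    report_rows = []
    col_pos = pd.Series(np.arange(len(lfc.columns)), index=lfc.columns)
    for gene, guides in genes.groupby(genes, sort=True).groups.items():
        cols = col_pos.loc[guides].to_numpy()
        if len(cols) < 2:
            n_single += len(cols)
            continue
        block = filled[:, cols]  # (replicates, guides of this gene)
        order = np.argsort(-block, axis=1, kind="stable")
        top_j = order[:, 0]
        rows = np.arange(block.shape[0])
        top = block[rows, top_j]
        second = block[rows, order[:, 1]]
        gap = top - second
        with np.errstate(invalid="ignore"):
            hit = (top > lfc_threshold) & (gap > gap_threshold) & np.isfinite(gap)
        for r in np.nonzero(hit)[0]:
            c = cols[top_j[r]]
            report_rows.append(
                {
                    "sequence_ID": lfc.index[r],
                    "sgrna": lfc.columns[c],
                    "gene": gene,
                    "lfc": values[r, c],
                    "gap": gap[r],
                }
            )
    if n_single:
        logger.info(
            "%d guides target single-guide genes and are exempt from outgrowth masking",
            n_single,
        )
    report = pd.DataFrame(
        report_rows, columns=["sequence_ID", "sgrna", "gene", "lfc", "gap"]
    )

    masked = data.copy()
    if len(report):
        counts = masked.counts
        row_pos = counts.index.get_indexer(report["sequence_ID"])
        col_pos = counts.columns.get_indexer(report["sgrna"])
        arr = counts.to_numpy(dtype=float)
        arr[row_pos, col_pos] = np.nan
        masked.counts = pd.DataFrame(arr, index=counts.index, columns=counts.columns)
        total = arr.size
        logger.info(
            "masked %d/%d readcount entries (%.4f%%) as suspected clonal outgrowths",
            len(report),
            total,
            100.0 * len(report) / total,
        )
    return masked, report
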