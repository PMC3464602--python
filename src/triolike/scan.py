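"""Multi-SNP analysis driver and the tab-separated results table.

``analyse_snps`` fits a null and an alternative model per SNP, forms the
likelihood-ratio test, and assembles one results row per SNP in input
order.  Degenerate SNPs (no tables, empty tables, monomorphic markers)
are reported as skipped with a reason, never dropped silently.  A batch
range restricts which SNPs are fitted, so a scan can be split across
processes and the rows concatenated.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cells import UnitType
from .likelihood import CountTable
from .model import TrioModel, likelihood_ratio_test
from .params import ModelSpec
from .pedio import MarkerInfo

__all__ = ["analyse_snps", "write_results_table", "read_results_table"]


def analyse_snps(
    tables: Mapping[str, Mapping[UnitType, CountTable]],
    null_spec: ModelSpec,
    alt_spec: ModelSpec,
    markers: Optional[Mapping[str, MarkerInfo]] = None,
    snp_order: Optional[Sequence[str]] = None,
    batch: Optional[tuple[int, int]] = None,
) -> pd.DataFrame:
    """Fit null/alternative models and LRT for each SNP.

    Parameters
    ----------
    tables : per-SNP unit count tables (as produced by extraction).
    null_spec, alt_spec : nested model specifications.
    markers : optional per-SNP marker info (risk allele, starting
        frequency for the HWE assumption).
    snp_order : explicit SNP ordering (defaults to ``tables`` order).
    batch : optional 1-based inclusive (first, last) range over the SNP
        order, for splitting a scan into parallel batches.

    Returns a DataFrame with one row per analysed SNP: identifiers,
    log-likelihoods, the LRT (stat, df, p) and one estimate/SE column
    pair per free alternative-model parameter.  Skipped SNPs carry a
    reason in ``status`` and NA elsewhere.
    """
    if not null_spec.nests(alt_spec):
        raise ValueError("null_spec must be nested in alt_spec")
    markers = markers or {}
    order = list(snp_order) if snp_order is not None else list(tables)
    if batch is not None:
        first, last = batch
        if not (1 <= first <= last <= len(order)):
            raise ValueError(
                f"batch range {batch} invalid for {len(order)} SNPs"
            )
        order = order[first - 1 : last]

    est_names = alt_spec.free_names
    rows = []
    for sid in order:
        marker = markers.get(sid)
        row: dict[str, object] = {
            "snp": sid,
            "risk_allele": marker.risk_allele if marker else "NA",
        }
        per_snp = tables.get(sid, {})
        snp_tables = [t for t in per_snp.values() if t.n_units > 0]
        row["n_units"] = sum(t.n_units for t in snp_tables)
        reason = None
        if not snp_tables:
            reason = "no_data"
        elif marker is not None and not marker.risk_allele:
            reason = "monomorphic"
        if reason is not None:
            row["status"] = f"skipped:{reason}"
            rows.append(row)
            continue
        freq = marker.frequency if marker and np.isfinite(marker.frequency) else None
        try:
            null_fit = TrioModel(snp_tables, null_spec, freq_start=freq).fit()
            alt_fit = TrioModel(snp_tables, alt_spec, freq_start=freq).fit()
            test = likelihood_ratio_test(null_fit, alt_fit)
        except (ValueError, FloatingPointError) as exc:
            row["status"] = f"skipped:fit_error:{exc}"
            rows.append(row)
            continue
        row.update(
            status="ok" if (null_fit.converged and alt_fit.converged) else "not_converged",
            loglik_null=null_fit.llf,
            loglik_alt=alt_fit.llf,
            n_free_null=null_fit.n_free,
            n_free_alt=alt_fit.n_free,
            lrt=test.lrt_stat,
            df=test.df,
            p=test.p_value,
        )
        for name in est_names:
            row[f"est_{name}"] = alt_fit.params[name]
            row[f"se_{name}"] = (
                alt_fit.bse[name] if alt_fit.bse is not None else np.nan
            )
        rows.append(row)

    columns = ["snp", "risk_allele", "n_units", "status", "loglik_null",
               "loglik_alt", "n_free_null", "n_free_alt", "lrt", "df", "p"]
    for name in est_names:
        columns += [f"est_{name}", f"se_{name}"]
    return pd.DataFrame(rows, columns=columns)


def write_results_table(df: pd.DataFrame, path) -> None:
    """Write the results table as TSV with a mandatory header row and
    'NA' for missing values."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
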