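"""ChIP-qPCR percent-recovery and proteomics enrichment-filter rules.

Small quantification formulas used alongside the sequencing analyses:
percent DNA recovered relative to input assuming perfect doubling per
cycle, no-antibody background subtraction, and the label-free proteomics
retention filter (unique-peptide floor, detection in every replicate,
+Ab/-Ab enrichment ratio with low-value imputation of missing abundances).
"""

from __future__ import annotations

import math
import warnings
from typing import List, Optional

import numpy as np
import pandas as pd

CT_RANGE = (5.0, 40.0)


def percent_dna(ct_input: float, ct_test: float) -> float:
    """Percent of input DNA recovered: 2^(Ct(input) - Ct(test)) x 100.

    Assumes exactly 2-fold amplification per cycle. Values outside the
    typical Ct range, or recoveries above 100%, trigger a warning but are
    returned as computed.
    """
    for name, ct in (("ct_input", ct_input), ("ct_test", ct_test)):
        if not math.isfinite(ct):
            raise ValueError(f"{name} must be finite")
        if not (CT_RANGE[0] <= ct <= CT_RANGE[1]):
            warnings.warn(
                f"{name}={ct} outside the typical Ct range {CT_RANGE}", stacklevel=2
            )
    value = 2.0 ** (ct_input - ct_test) * 100.0
    if value > 100.0:
        warnings.warn(f"recovery {value:.4g}% exceeds 100% of input", stacklevel=2)
    return value


def background_subtract(percent_ab: float, percent_noab: float) -> float:
    """Subtract the no-antibody recovery; negative results are flagged, not clamped."""
    if percent_ab < 0 or percent_noab < 0:
        raise ValueError("percent recoveries must be >= 0")
    value = percent_ab - percent_noab
    if value < 0:
        warnings.warn(
            f"background-subtracted recovery is negative ({value:.4g}%)", stacklevel=2
        )
    return value


# proteomics table columns: protein, then per replicate r in 1..n_replicates:
#   unique_peptides_rep{r}, ab_rep{r}, noab_rep{r}   (NaN = not observed)


def proteomics_filter(
    records: pd.DataFrame,
    min_unique: int = 2,
    min_ratio: float = 5.0,
    n_replicates: int = 2,
    ratio_mode: str = "per_replicate",
    imputation_factor: float = 0.5,
) -> pd.DataFrame:
    """Retain proteins enriched by antibody pulldown across replicates.

    1. Missing abundances are imputed as ``imputation_factor`` times the
       minimum observed abundance in that replicate/channel column.
    2. Proteins with fewer than ``min_unique`` unique peptides in any
       replicate are removed.
    3. Proteins not detected (+Ab abundance observed) in every replicate
       are removed.
    4. Retained iff +Ab / -Ab >= ``min_ratio`` in every replicate
       (``ratio_mode='per_replicate'``, default) or on the mean of the
       per-replicate ratios (``ratio_mode='mean'``).

    Returns the retained rows with imputed abundances and ratio columns.
    """
    if ratio_mode not in ("per_replicate", "mean"):
        raise ValueError("ratio_mode must be 'per_replicate' or 'mean'")
    if min_unique < 0 or min_ratio < 0 or n_replicates < 1:
        raise ValueError("thresholds must be non-negative, n_replicates >= 1")
    reps = range(1, n_replicates + 1)
    needed = ["protein"] + [
        f"{col}_rep{r}" for r in reps for col in ("unique_peptides", "ab", "noab")
    ]
    missing = set(needed) - set(records.columns)
    if missing:
        raise ValueError(f"proteomics table missing columns: {sorted(missing)}")

    df = records.copy()
    detected = pd.Series(True, index=df.index)
    for r in reps:
        detected &= df[f"ab_rep{r}"].notna()

    for r in reps:
        for channel in ("ab", "noab"):
            col = f"{channel}_rep{r}"
            observed = df[col].dropna()
            if observed.empty:
                raise ValueError(f"no observed abundances in column {col!r}")
            floor = imputation_factor * float(observed.min())
            if floor <= 0 and channel == "noab":
                raise ValueError(
                    f"imputation floor for {col!r} is not positive; "
                    "ratios against it are undefined"
                )
            df[col] = df[col].fillna(floor)

    keep = detected
    for r in reps:
        keep &= df[f"unique_peptides_rep{r}"].fillna(0) >= min_unique

    ratios = []
    for r in reps:
        noab = df[f"noab_rep{r}"]
        if (noab <= 0).any():
            raise ValueError("zero -Ab abundance after imputation")
        ratio = df[f"ab_rep{r}"] / noab
        df[f"ratio_rep{r}"] = ratio
        ratios.append(ratio)
    ratio_frame = pd.concat(ratios, axis=1)
    if ratio_mode == "per_replicate":
        keep &= (ratio_frame >= min_ratio).all(axis=1)
    else:
        keep &= ratio_frame.mean(axis=1) >= min_ratio
    return df.loc[keep].reset_index(drop=True)


def qpcr_table(
    table: pd.DataFrame,
    ct_input_col: str = "ct_input",
    ct_test_col: str = "ct_test",
    ct_noab_col: Optional[str] = "ct_noab",
) -> pd.DataFrame:
    """Apply percent_dna (and no-antibody subtraction when present) row-wise."""
    out = table.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["percent_dna"] = [
            percent_dna(float(r[ct_input_col]), float(r[ct_test_col]))
            for _, r in table.iterrows()
        ]
        if ct_noab_col is not None and ct_noab_col in table.columns:
            noab_pct: List[float] = []
            corrected: List[float] = []
            for pct, (_, r) in zip(out["percent_dna"], table.iterrows()):
                ct_noab = r[ct_noab_col]
                if pd.isna(ct_noab):
                    noab_pct.append(np.nan)
                    corrected.append(pct)
                else:
                    npct = percent_dna(float(r[ct_input_col]), float(ct_noab))
                    noab_pct.append(npct)
                    corrected.append(background_subtract(pct, npct))
            out["percent_dna_noab"] = noab_pct
            out["percent_dna_corrected"] = corrected
    return out
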