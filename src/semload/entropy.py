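"""Per-sample Shannon entropy of the methylome.

Entropy here is the normalized average binary entropy of a sample's beta
values:

    H = 1 / (N * log2(1/2)) * sum_i [ b_i*log2(b_i) + (1-b_i)*log2(1-b_i) ]

with the convention 0*log2(0) = 0.  It equals 1 when every site is
half-methylated (the methylome maximally unpredictable across the cell
population) and 0 when every site is fully methylated or unmethylated.
N counts the probes actually used for the sample; missing values are
skipped with N reduced accordingly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_EPS = 1e-12  # guard against -inf*0 artifacts from float rounding near 0/1


def methylome_entropy(beta) -> pd.DataFrame:
    """Return a per-sample table with columns ``entropy`` and
    ``n_probes_used``.  A sample with zero usable probes gets NaN."""
    values = beta.values.to_numpy(dtype=float)
    n_used = np.sum(~np.isnan(values), axis=0)
    # Exact 0/1 contribute 0 by convention; clip only to stabilize logs.
    b = np.clip(values, _EPS, 1 - _EPS)
    terms = b * np.log2(b) + (1 - b) * np.log2(1 - b)
    terms = np.where(np.isnan(values), 0.0, terms)
    with np.errstate(invalid="ignore", divide="ignore"):
        entropy = terms.sum(axis=0) / (n_used * np.log2(0.5))
    entropy = np.where(n_used == 0, np.nan, entropy)
    out = pd.DataFrame(
        {"entropy": entropy, "n_probes_used": n_used}, index=beta.sample_ids
    )
    out.index.name = "sample_id"
    return out
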