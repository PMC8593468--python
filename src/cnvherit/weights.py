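"""Per-animal weights on deregressed EBVs.

The weight of animal i follows Garrick's derivation for deregressed
proofs used as pseudo-phenotypes:

    w_i = (1 − h²) / ([c + (1 − r_i²)/r_i²] · h²)

where h² is the trait heritability, r_i² the reliability of the animal's
EBV and c the fraction of genetic variance not accounted for by the
markers (default 0.9).  The residual covariance of the mixed models is
D⁻¹σe² with D = diag(w).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def garrick_weight(h2, r2, c: float = 0.9):
    """Weight(s) on deregressed EBVs; vectorized over ``r2``.

    Parameters
    ----------
    h2 : trait heritability, in (0, 1)
    r2 : EBV reliability per animal, in (0, 1]
    c : fraction of genetic variance not explained by markers, >= 0
    """
    h2 = float(h2)
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"heritability must be in (0,1), got {h2}")
    if c < 0:
        raise ValueError("c must be non-negative")
    r2 = np.asarray(r2, dtype=float)
    if (r2 <= 0).any() or (r2 > 1).any():
        raise ValueError("reliability must be in (0, 1]")
    w = (1.0 - h2) / ((c + (1.0 - r2) / r2) * h2)
    return float(w) if w.ndim == 0 else w


def add_weights(traits: pd.DataFrame, h2: float, c: float = 0.9) -> pd.DataFrame:
    """Return the trait table with a ``weight`` column appended."""
    if "reliability" not in traits.columns:
        raise ValueError("trait table has no 'reliability' column")
    out = traits.copy()
    out["weight"] = garrick_weight(h2, out["reliability"].to_numpy(), c)
    return out
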