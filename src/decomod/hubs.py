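"""Hub-gene ranking: module members at the extremes of the signature.

With standardized signatures the genes with the largest absolute weights are
the ones driving the component, so hubness is operationalized as largest
|weight| among a module's members, both tails eligible.  Ties are broken by
gene id (lexicographic) so output is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assign import ModuleSet

__all__ = ["HubGeneReport", "top_hub_genes"]


@dataclass
class HubGeneReport:
    n_hub: int
    per_module: dict[str, pd.DataFrame]  # module id -> [gene, weight, rank]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for m, df in self.per_module.items():
            block = df.copy()
            block.insert(0, "module", m)
            frames.append(block)
        return pd.concat(frames, ignore_index=True)


def top_hub_genes(M: ModuleSet, n_hub: int = 10) -> HubGeneReport:
    """Top ``min(n_hub, module size)`` members per module by |weight|."""
    if n_hub < 1:
        raise ValueError(f"n_hub must be ≥ 1, got {n_hub}")
    per_module: dict[str, pd.DataFrame] = {}
    for m in M.module_ids:
        genes = M.module_genes(m)
        w = M.weights.loc[genes, m]
        order = sorted(genes, key=lambda g: (-abs(w[g]), g))
        top = order[: min(n_hub, len(order))]
        per_module[m] = pd.DataFrame(
            {
                "gene": top,
                "weight": [float(w[g]) for g in top],
                "rank": np.arange(1, len(top) + 1),
            }
        )
    return HubGeneReport(n_hub=n_hub, per_module=per_module)
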