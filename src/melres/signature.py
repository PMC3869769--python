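"""Gene signatures: ordered probe lists with discovery weights and Cox reweights.

A :class:`GeneSignature` holds one row per probe set with the columns used
throughout the pipeline: the probe identifier, optional gene symbol and
chromosomal location, the discovery-stage regression ``weight`` (from the
cell-line GI50 fit) and the training-cohort Cox ``new_weight``.  The on-disk
layout mirrors the tab-separated table written by :mod:`melres.io`.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import EmptySignatureError

COLUMNS = ("probe_id", "gene_symbol", "location", "weight", "new_weight")


class GeneSignature:
    """An ordered list of probes with per-probe weights.

    Parameters
    ----------
    table : pandas.DataFrame or iterable of mappings
        Must provide ``probe_id`` and ``weight``; ``gene_symbol``,
        ``location`` and ``new_weight`` are optional.  Row order is
        preserved.
    dropped_probes : sequence of str, optional
        Probes removed during reweighting (zero expression variance);
        recorded for reporting only.
    """

    def __init__(self, table, dropped_probes: Iterable[str] = ()):
        frame = pd.DataFrame(table).copy()
        if "probe_id" not in frame.columns or "weight" not in frame.columns:
            raise ValueError("signature table requires 'probe_id' and 'weight' columns")
        for col, default in (("gene_symbol", ""), ("location", ""), ("new_weight", np.nan)):
            if col not in frame.columns:
                frame[col] = default
        frame = frame.loc[:, list(COLUMNS)]
        frame["probe_id"] = frame["probe_id"].astype(str)
        if len(frame) == 0:
            raise EmptySignatureError("signature contains no probes")
        if frame["probe_id"].duplicated().any():
            dups = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"duplicate probe ids in signature: {dups}")
        frame["weight"] = frame["weight"].astype(float)
        frame["new_weight"] = frame["new_weight"].astype(float)
        if not np.isfinite(frame["weight"]).all():
            raise ValueError("signature weights must be finite")
        self._frame = frame.reset_index(drop=True)
        self.dropped_probes = tuple(dropped_probes)

    def __len__(self) -> int:
        return len(self._frame)

    def __repr__(self) -> str:
        status = "reweighted" if self.has_new_weights else "discovery-stage"
        return f"GeneSignature({len(self)} probes, {status})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSignature):
            return NotImplemented
        return self._frame.equals(other._frame)

    @property
    def probe_ids(self) -> list[str]:
        return self._frame["probe_id"].tolist()

    @property
    def weights(self) -> pd.Series:
        """Discovery-stage coefficients indexed by probe id."""
        return pd.Series(
            self._frame["weight"].to_numpy(), index=self.probe_ids, name="weight"
        )

    @property
    def new_weights(self) -> pd.Series:
        """Training-cohort Cox coefficients indexed by probe id (NaN if unset)."""
        return pd.Series(
            self._frame["new_weight"].to_numpy(), index=self.probe_ids, name="new_weight"
        )

    @property
    def has_new_weights(self) -> bool:
        return bool(np.isfinite(self._frame["new_weight"]).all())

    def with_new_weights(
        self, new_weights: Mapping[str, float], dropped_probes: Iterable[str] = ()
    ) -> "GeneSignature":
        """Return a copy restricted to ``new_weights`` keys, in original order."""
        dropped = tuple(dropped_probes)
        keep = self._frame["probe_id"].isin(set(new_weights))
        frame = self._frame.loc[keep].copy()
        if len(frame) == 0:
            raise EmptySignatureError("no probes retained after reweighting")
        frame["new_weight"] = [float(new_weights[p]) for p in frame["probe_id"]]
        return GeneSignature(frame, dropped_probes=dropped)

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()
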