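"""Inflammatory marker panel metadata.

The default panel mirrors a 17-marker plasma panel spanning three assay
platforms: a multiplex electrochemiluminescence ELISA (cytokines, CRP and
adhesion molecules, run in duplicate), two singlet ELISAs (suPAR, A2M) and a
proximity-extension assay (soluble cytokine receptors and CD93, reported on a
log-linear NPX-like scale). Per-marker limits of detection (LOD) and the
duplicate-assayed flag drive the quality-control and substitution rules in
:mod:`immunotype.preprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["MarkerPanel", "default_panel", "MARKERS", "EFFECT_SIZES"]

#: Panel marker names, ordered by platform block
#: (multiplex ELISA, singlet ELISA, PEA).
MARKERS: tuple[str, ...] = (
    "IFN-gamma",
    "TNF-alpha",
    "IL-6",
    "IL-8",
    "IL-10",
    "CRP",
    "sICAM-1",
    "sVCAM-1",
    "suPAR",
    "A2M",
    "IL-1RT1",
    "IL-1RT2",
    "IL-2RA",
    "IL-6RA",
    "TNFR1",
    "TNFR2",
    "CD93",
)

#: Standardised subgroup-2 minus subgroup-1 mean differences used as the
#: default effect vector of the synthetic cohort generator (pooled z-scale).
EFFECT_SIZES: dict[str, float] = {
    "IFN-gamma": 0.26,
    "IL-10": 0.29,
    "IL-6RA": 0.30,
    "IL-8": 0.35,
    "A2M": 0.40,
    "IL-6": 0.44,
    "sVCAM-1": 0.52,
    "IL-1RT2": 0.55,
    "TNF-alpha": 0.58,
    "CRP": 0.60,
    "IL-1RT1": 0.74,
    "sICAM-1": 0.79,
    "IL-2RA": 1.01,
    "CD93": 1.03,
    "suPAR": 1.15,
    "TNFR1": 1.31,
    "TNFR2": 1.47,
}

_PLATFORM = {m: "multiplex_elisa" for m in MARKERS[:8]}
_PLATFORM.update({"suPAR": "singlet_elisa", "A2M": "singlet_elisa"})
_PLATFORM.update({m: "pea" for m in MARKERS[10:]})


@dataclass
class MarkerPanel:
    """Per-marker assay metadata.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per marker with columns ``marker``, ``lod``, ``platform``
        and ``duplicate_assayed``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"marker", "lod", "platform", "duplicate_assayed"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    @property
    def lod(self) -> pd.Series:
        return self.table.set_index("marker")["lod"]

    @property
    def duplicate_assayed(self) -> pd.Series:
        return self.table.set_index("marker")["duplicate_assayed"]

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MarkerPanel":
        return cls(pd.read_csv(path, sep="\t"))


def default_panel(lod: dict[str, float] | None = None) -> MarkerPanel:
    """Build the default 17-marker panel.

    Parameters
    ----------
    lod : dict, optional
        Per-marker limits of detection. Defaults to ``nan`` (set by the
        synthetic generator from the simulated marginals, or supplied by the
        user for real data).
    """
    lod = lod or {}
    rows = [
        {
            "marker": m,
            "lod": lod.get(m, float("nan")),
            "platform": _PLATFORM[m],
            "duplicate_assayed": _PLATFORM[m] == "multiplex_elisa",
        }
        for m in MARKERS
    ]
    return MarkerPanel(pd.DataFrame(rows))
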