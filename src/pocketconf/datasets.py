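"""Packaged reference tables.

``vdr_calcitriol_transitions`` is the published TD-DFT characterization of
the predominant electronic transition of calcitriol, the aromatic pocket
residues TRP286/TYR295, and their complexes (wavelength of the most intense
singlet excitation, oscillator strength, transition dipole in debye).  The
table is an *input* to the spectral post-processing here, not something this
package computes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .spectra import TransitionRecord

__all__ = ["vdr_calcitriol_transitions", "VDR_KD_MOLAR"]

#: experimentally reported dissociation constant of the VDR-calcitriol
#: complex for the crystallographic construct, mol/L
VDR_KD_MOLAR = 0.37e-9


def _load_table() -> pd.DataFrame:
    with resources.files("pocketconf.data").joinpath(
        "vdr_calcitriol_transitions.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def vdr_calcitriol_transitions(system: str | None = None) -> list[TransitionRecord]:
    """Transition records, optionally filtered to one system label
    (e.g. ``'calcitriol'`` or ``'calcitriol-TRP286-TYR295'``)."""
    df = _load_table()
    if system is not None:
        df = df[df["system"] == system]
        if df.empty:
            known = sorted(_load_table()["system"].unique())
            raise KeyError(f"unknown system {system!r}; known: {known}")
    records = []
    for _, row in df.iterrows():
        records.append(
            TransitionRecord(
                state=int(row["state"]),
                lambda_nm=float(row["lambda_nm"]),
                f=float(row["f"]),
                mu_tr=float(row["mu_tr_D"]),
                assignment=str(row["assignment"]),
                character=tuple(str(row["character"]).split(",")),
                weight_percent=float(row["percent"]),
                predominant=bool(row["predominant"]),
            )
        )
    return records
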