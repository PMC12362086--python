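"""asdkit: drug-polymer solubility and miscibility modeling for
amorphous solid dispersions.

Turns DSC-style melting-point-depression and glass-transition datasets
into annotated temperature-composition phase diagrams via group-
contribution screening, Flory-Huggins analysis, the Kyeremateng empirical
fit, a PC-SAFT equation of state, and Gordon-Taylor/Kwei Tg models.
"""
from importlib import resources as _resources
from pathlib import Path as _Path

from .core import (
    R,
    CompoundThermo,
    Composition,
    FitReport,
    MPDDataset,
    Role,
    TgDataset,
    aard,
    ard,
    convert_composition,
    load_compounds,
    load_mpd,
    load_tg,
)

__version__ = "0.1.0"


def default_compounds() -> dict[str, CompoundThermo]:
    """The bundled ibuprofen + four-polymer compound registry."""
    return load_compounds(_Path(_resources.files("asdkit").joinpath("data", "compounds.json")))
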