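"""Packaged example data.

A five-purchase worked example (one person buying 10-DDD packs at
gaps of 10, 5, 15 and 10 days — a stockpiling pattern at an average
dose of one DDD per day) together with a minimal parameter-file set,
so the toolkit can be exercised offline out of the box.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import Purchase, read_purchases
from .parameters import ParameterSpace, load_parameter_space

__all__ = ["data_path", "load_example_history", "load_example_parameters"]


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("pre2dup.data") / name)


def load_example_history() -> list[Purchase]:
    """The packaged five-purchase stockpiling example."""
    return read_purchases(data_path("stockpiling_example_purchases.csv"))


def load_example_parameters() -> ParameterSpace:
    """The packaged minimal parameter set matching the example."""
    return load_parameter_space(
        global_file=data_path("params_global.yaml"),
        atc_file=data_path("params_atc.yaml"),
        vnr_file=data_path("params_vnr.yaml"),
    )
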