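"""Run configuration shared by the CLI and pipeline stages.

A run is reproducible from its :class:`RunConfig` plus the seed; the config is
serialized into every output bundle.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Union

import yaml

log = logging.getLogger("sigprof")


@dataclass
class RunConfig:
    """Parameters controlling a simulate/analyze run.

    Attributes
    ----------
    seed:
        Master seed for all pseudorandom streams in the run.
    qc_min_dff:
        Minimum post-stimulus ΔF/F for a cell to be retained (cells below it
        are removed before fitting/clustering in cAMP pipelines).
    k_min, k_max:
        Inclusive range of candidate cluster numbers scored with the PBM index.
    restarts:
        Independent k-means initializations per candidate K.
    znorm:
        Whether to z-normalize each trace before clustering (off by default:
        the response families differ chiefly by amplitude).
    peak_align:
        Align traces at the per-cell peak instead of the stimulus time.
    noise_sd:
        Additive Gaussian noise SD (ΔF/F units) for synthetic traces.
    n_cells:
        Cells per synthetic trace set.
    n_wells:
        Wells the synthetic cells are distributed over (round robin).
    min_nucleus_area:
        Minimum connected-component area (px) kept by nuclear segmentation.
    green_threshold:
        Per-nucleus mean-green threshold for calling a cell stressed: a number,
        or ``"auto"`` (Otsu when the pooled distribution is bimodal, else 3x
        the background green level).
    """

    seed: int = 0
    qc_min_dff: float = 0.2
    k_min: int = 2
    k_max: int = 7
    restarts: int = 25
    znorm: bool = False
    peak_align: bool = False
    noise_sd: float = 0.05
    n_cells: int = 800
    n_wells: int = 3
    min_nucleus_area: int = 20
    green_threshold: Union[str, float] = "auto"
    outdir: str = "sigprof_run"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
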