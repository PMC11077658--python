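"""Demographic model family and simulation configuration.

The model family covers two contemporary demes ("ES" and "IQ") that split
from a common ancestral population ``t_div`` generations before present.
The ancestral population has one, two or three constant-size epochs
(one-epoch "A", two-epoch "B", three-epoch "C" demographies), and the two
contemporary demes may be strictly isolated (SI), or connected by symmetric
or asymmetric migration (IM).  All population sizes are HAPLOID lineage
counts (the convention in which a pair of lineages in a deme of size N
coalesces at rate 1/N per generation); diploid individuals are formed
downstream by pairing haplotypes.  Time runs backwards, in generations
before present, and migration rates are backwards rates: a lineage
currently in deme i jumps to deme j at rate ``migration[i][j]`` per
generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DemographicModel",
    "SimConfig",
    "MODEL_IDS",
    "MODEL_K",
    "free_parameters",
    "build_model",
]

#: mutation rate per site per generation estimated for Anatidae
DEFAULT_MU = 4.83e-9
#: species generation time in years
DEFAULT_GENERATION_TIME = 4.0


@dataclass(frozen=True)
class DemographicModel:
    """Two-deme divergence model with a piecewise-constant ancestral history.

    Parameters
    ----------
    theta_es, theta_iq:
        Contemporary haploid sizes of the two demes.
    t_div:
        Split time in generations before present (0 allowed: panmixia).
    theta_anc:
        Haploid size of the ancestral population immediately after (looking
        backwards) the split.
    migration:
        2x2 backwards migration rate matrix between the contemporary demes,
        per generation.  ``migration[0][1]`` is the rate at which an ES
        lineage jumps into IQ.  All zero means strict isolation.
    anc_epochs:
        Additional ancestral size changes as ``(time, size)`` pairs with
        strictly increasing times, all > ``t_div``.  Empty for one-epoch
        ("A") demographies; one entry ``(t_bot1, theta_bot1)`` for "B";
        two entries for "C".
    """

    theta_es: float
    theta_iq: float
    t_div: float
    theta_anc: float
    migration: tuple = ((0.0, 0.0), (0.0, 0.0))
    anc_epochs: tuple = ()
    demes: tuple = ("ES", "IQ")

    def __post_init__(self) -> None:
        for name in ("theta_es", "theta_iq", "theta_anc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.t_div < 0:
            raise ValueError("t_div must be >= 0")
        m = np.asarray(self.migration, dtype=float)
        if m.shape != (2, 2) or (m < 0).any():
            raise ValueError("migration must be a non-negative 2x2 matrix")
        last = self.t_div
        for t, size in self.anc_epochs:
            if t <= last:
                raise ValueError(
                    "ancestral epoch times must be strictly increasing and > t_div"
                )
            if size <= 0:
                raise ValueError("ancestral epoch sizes must be > 0")
            last = t

    @property
    def is_isolation(self) -> bool:
        return not np.any(np.asarray(self.migration))

    def ancestral_sizes_times(self) -> tuple[np.ndarray, np.ndarray]:
        """Epoch change times (ascending, starting at t_div) and sizes."""
        times = [self.t_div] + [t for t, _ in self.anc_epochs]
        sizes = [self.theta_anc] + [s for _, s in self.anc_epochs]
        return np.asarray(times, float), np.asarray(sizes, float)


@dataclass
class SimConfig:
    """Settings shared by the synthetic-data generators.

    Defaults emulate the study system: a ddRAD-like panel of thousands of
    short unlinked loci genotyped for 24 ES + 12 IQ diploid individuals,
    with a modest rate of missing calls, and a short (169 bp) mtDNA
    control-region fragment.
    """

    mu: float = DEFAULT_MU
    generation_time: float = DEFAULT_GENERATION_TIME
    seed: int = 1
    n_loci: int = 75_000
    locus_length: int = 140
    missing_rate: float = 0.02
    samples_per_deme: tuple = (24, 12)  # diploid individuals
    mt_seq_length: int = 169
    mt_mu: float = 2.0e-6
    mt_ne_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be > 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if any(s < 1 for s in self.samples_per_deme):
            raise ValueError("need at least one sample per deme")


# ---------------------------------------------------------------------------
# The nine-model family: A/B/C = 1/2/3 ancestral epochs, 1/2/3 = SI/IM_S/IM_A

MODEL_IDS = ("A1", "A2", "A3", "B1", "B2", "B3", "C1", "C2", "C3")

#: free-parameter count per model (theta_iq is fixed externally)
MODEL_K = {
    "A1": 3, "A2": 4, "A3": 5,
    "B1": 5, "B2": 6, "B3": 7,
    "C1": 7, "C2": 8, "C3": 9,
}

_MIGRATION_PARAMS = {"1": (), "2": ("m_sym",), "3": ("m_es_iq", "m_iq_es")}
_EPOCH_PARAMS = {
    "A": (),
    "B": ("theta_bot1", "t_bot1"),
    "C": ("theta_bot1", "t_bot1", "theta_bot2", "t_bot2"),
}


def free_parameters(model_id: str) -> tuple[str, ...]:
    """Names of the free parameters of a model, in canonical order."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    demo, mig = model_id[0], model_id[1]
    names = ("theta_anc", "theta_es", "t_div") + _EPOCH_PARAMS[demo] + _MIGRATION_PARAMS[mig]
    assert len(names) == MODEL_K[model_id]
    return names


def build_model(model_id: str, params: dict, theta_iq: float) -> DemographicModel:
    """Instantiate a :class:`DemographicModel` from a named parameter dict.

    ``params`` must contain exactly the :func:`free_parameters` of
    ``model_id``; ``theta_iq`` is the externally fixed contemporary size of
    the IQ deme.
    """
    names = free_parameters(model_id)
    missing = set(names) - set(params)
    extra = set(params) - set(names)
    if missing or extra:
        raise ValueError(
            f"model {model_id}: missing parameters {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    mig_kind = model_id[1]
    if mig_kind == "1":
        migration = ((0.0, 0.0), (0.0, 0.0))
    elif mig_kind == "2":
        m = params["m_sym"]
        migration = ((0.0, m), (m, 0.0))
    else:
        migration = ((0.0, params["m_es_iq"]), (params["m_iq_es"], 0.0))
    epochs = []
    if model_id[0] in ("B", "C"):
        epochs.append((params["t_bot1"], params["theta_bot1"]))
    if model_id[0] == "C":
        epochs.append((params["t_bot2"], params["theta_bot2"]))
    return DemographicModel(
        theta_es=params["theta_es"],
        theta_iq=theta_iq,
        t_div=params["t_div"],
        theta_anc=params["theta_anc"],
        migration=migration,
        anc_epochs=tuple(epochs),
    )
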