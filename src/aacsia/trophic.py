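"""Trophic position estimation from paired trophic/source amino acid d15N.

The estimator is the standard source-trophic amino acid framework

    TP = ((d15N_trophic - d15N_source) - beta) / TDF + 1

where beta is the producer-level offset between the trophic and source
amino acid at the base of the food web and TDF the trophic
discrimination factor (per-trophic-step enrichment of the trophic
relative to the source amino acid). Two literature parameterizations are
shipped as presets:

* ``GlxPhe``: Glx vs Phe, beta = 3.4 permil, TDF = 7.6 permil —
  metazoan trophic transfer.
* ``AlaPhe``: Ala vs Phe, beta = 3.2 permil, TDF = 4.5 permil —
  additionally integrates protistan/microzooplankton grazing steps.

Arbitrary (trophic AA, source AA, beta, TDF) quadruples are accepted;
beta and TDF are treated as fixed constants, so first-order uncertainty
propagation from replicate SDs is sqrt(sd_t^2 + sd_s^2)/TDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .datamodel import AMINO_ACIDS, Dataset
from .exceptions import DomainError, EmptyResultError, SchemaError


@dataclass(frozen=True)
class TPParameterization:
    """Named (trophic AA, source AA, beta, TDF) quadruple."""

    name: str
    trophic_aa: str
    source_aa: str
    beta: float
    tdf: float

    def __post_init__(self):
        if self.trophic_aa not in AMINO_ACIDS:
            raise SchemaError(f"unknown trophic amino acid {self.trophic_aa!r}")
        if self.source_aa not in AMINO_ACIDS:
            raise SchemaError(f"unknown source amino acid {self.source_aa!r}")
        if not (self.tdf > 0):
            raise DomainError(f"TDF must be > 0, got {self.tdf}")


GLX_PHE = TPParameterization("GlxPhe", "Glx", "Phe", beta=3.4, tdf=7.6)
ALA_PHE = TPParameterization("AlaPhe", "Ala", "Phe", beta=3.2, tdf=4.5)
PRESETS: dict[str, TPParameterization] = {"GlxPhe": GLX_PHE, "AlaPhe": ALA_PHE}


@dataclass(frozen=True)
class TPEstimate:
    """A trophic-position estimate for one sample under one parameterization."""

    sample_id: str
    parameterization: str
    tp: float
    tp_sd: float | None = None


def estimate_tp(d15n_trophic: float, d15n_source: float,
                params: TPParameterization) -> float:
    """Point estimate of trophic position.

    TP = 1 exactly when the trophic-source difference equals beta
    (an organism at the producer baseline).
    """
    return ((d15n_trophic - d15n_source) - params.beta) / params.tdf + 1.0


def propagate_tp_sd(sd_trophic: float, sd_source: float,
                    params: TPParameterization) -> float:
    """First-order SD of TP from the two replicate SDs.

    beta and TDF are fixed constants, so
    sd_TP = sqrt(sd_trophic^2 + sd_source^2) / TDF.
    """
    if sd_trophic < 0 or sd_source < 0:
        raise DomainError("replicate SDs must be >= 0")
    return math.hypot(sd_trophic, sd_source) / params.tdf


def batch_tp(dataset: Dataset, params: TPParameterization):
    """Estimate TP for every record holding both required d15N values.

    Returns ``(estimates, skipped)``; ``skipped`` lists
    ``(sample_id, reason)`` for records missing either amino acid.
    ``tp_sd`` is attached whenever both measurements carry replicate SDs.
    Raises :class:`EmptyResultError` if no record qualifies.
    """
    estimates: list[TPEstimate] = []
    skipped: list[tuple[str, str]] = []
    for rec in dataset:
        mt = rec.get(params.trophic_aa, "d15N")
        ms = rec.get(params.source_aa, "d15N")
        if mt is None or ms is None:
            missing = params.trophic_aa if mt is None else params.source_aa
            skipped.append((rec.sample_id, f"missing d15N for {missing}"))
            continue
        tp = estimate_tp(mt.value, ms.value, params)
        sd = propagate_tp_sd(mt.sd, ms.sd, params)
        estimates.append(TPEstimate(rec.sample_id, params.name, tp, sd))
    if not estimates:
        raise EmptyResultError(
            f"no record holds d15N for both {params.trophic_aa} and "
            f"{params.source_aa} ({params.name})"
        )
    return estimates, skipped
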