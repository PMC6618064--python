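"""Contrast-level data containers and I/O for bivariate network meta-analysis.

Studies enter as two-arm contrasts: each row carries the effect difference
(experimental vs. baseline arm) on a surrogate endpoint (``y1``, e.g. a log
odds ratio of tumour response) and on a final outcome (``y2``, e.g. a log
hazard ratio of progression-free survival), together with their standard
errors and the within-study correlation between the two estimates.  The
final-outcome estimate may be missing, which is how a study is flagged for
prediction / cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """An input table does not have the required columns."""


class ValidationError(ValueError):
    """A row of an input table violates a range constraint."""


class StructuralError(ValueError):
    """The treatment network is malformed (e.g. disconnected)."""


REQUIRED_COLUMNS = (
    "study_id",
    "treat_k",
    "treat_l",
    "y1",
    "se1",
    "y2",
    "se2",
    "rho_w",
)


@dataclass(frozen=True)
class ContrastObservation:
    """One two-arm study's effect differences on both outcomes.

    ``treat_k`` is the baseline (control) arm and ``treat_l`` the
    experimental arm; effects are l vs. k on each outcome's analysis scale.
    ``y2 is None`` marks a missing final-outcome estimate (the standard
    error ``se2`` is still required, since it enters the predictive
    distribution when the effect is predicted).
    """

    study_id: str
    treat_k: str
    treat_l: str
    y1: float
    se1: float
    y2: float | None
    se2: float
    rho_w: float

    def __post_init__(self) -> None:
        if self.treat_k == self.treat_l:
            raise ValidationError(
                f"study {self.study_id!r}: arms must differ, got "
                f"{self.treat_k!r} twice"
            )
        for name in ("se1", "se2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(
                    f"study {self.study_id!r}: {name} must be a positive "
                    f"real, got {v!r}"
                )
        if not (math.isfinite(self.rho_w) and abs(self.rho_w) < 1):
            raise ValidationError(
                f"study {self.study_id!r}: rho_w must lie in (-1, 1), got "
                f"{self.rho_w!r}"
            )
        if not math.isfinite(self.y1):
            raise ValidationError(f"study {self.study_id!r}: y1 must be finite")
        if self.y2 is not None and not math.isfinite(self.y2):
            raise ValidationError(
                f"study {self.study_id!r}: y2 must be finite or missing"
            )

    @property
    def y2_missing(self) -> bool:
        return self.y2 is None

    @property
    def contrast(self) -> tuple[str, str]:
        """Unordered treatment pair, in lexical order."""
        return tuple(sorted((self.treat_k, self.treat_l)))  # type: ignore[return-value]


@dataclass(frozen=True)
class BetweenStudyCov:
    """Between-study heterogeneity of one contrast: (tau1, tau2, rho).

    The implied 2x2 covariance [[tau1^2, tau1 tau2 rho], [., tau2^2]] is
    positive semidefinite automatically for the admitted field ranges.
    """

    tau1: float
    tau2: float
    rho: float

    def __post_init__(self) -> None:
        if self.tau1 < 0 or self.tau2 < 0:
            raise ValidationError("tau1 and tau2 must be nonnegative")
        if abs(self.rho) > 1 + 1e-12:
            raise ValidationError(f"rho must lie in [-1, 1], got {self.rho}")

    @property
    def matrix(self) -> np.ndarray:
        off = self.tau1 * self.tau2 * self.rho
        return np.array([[self.tau1**2, off], [off, self.tau2**2]])


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summary of one scalar parameter ("mean (95% CrI)" style)."""

    name: str
    mean: float
    sd: float
    q2_5: float
    q50: float
    q97_5: float
    mcse: float
    ess: float
    rhat: float

    def __post_init__(self) -> None:
        if not (self.q2_5 <= self.q50 <= self.q97_5):
            raise ValidationError(
                f"{self.name}: quantiles must be ordered, got "
                f"({self.q2_5}, {self.q50}, {self.q97_5})"
            )
        if self.mcse < 0:
            raise ValidationError(f"{self.name}: MC error must be >= 0")


class NetworkData:
    """A validated collection of two-arm contrast observations.

    Treatments are ordered lexically unless an explicit order or reference
    is supplied; the reference treatment is first.  The ordering matters:
    basic parameters are effects vs. the reference, and the Cholesky-based
    prior of the second-order-consistency models depends on it.
    """

    def __init__(
        self,
        observations: Sequence[ContrastObservation],
        treatments: Sequence[str] | None = None,
        reference: str | None = None,
    ) -> None:
        obs = tuple(observations)
        if not obs:
            raise ValidationError("at least one observation is required")
        labels = sorted({t for o in obs for t in (o.treat_k, o.treat_l)})
        if treatments is None:
            treatments = labels
        else:
            treatments = list(treatments)
            missing = set(labels) - set(treatments)
            if missing:
                raise StructuralError(
                    f"observations reference treatments absent from the "
                    f"catalogue: {sorted(missing)}"
                )
        if reference is None:
            reference = treatments[0]
        elif reference not in treatments:
            raise StructuralError(f"reference {reference!r} not a treatment")
        order = [reference] + [t for t in treatments if t != reference]

        graph = nx.Graph()
        graph.add_nodes_from(order)
        graph.add_edges_from((o.treat_k, o.treat_l) for o in obs)
        if not nx.is_connected(graph):
            comps = [sorted(c) for c in nx.connected_components(graph)]
            raise StructuralError(
                f"treatment network is disconnected; components: {comps}"
            )

        self.observations = obs
        self.treatments = tuple(order)
        self.reference = reference
        self._index = {t: i for i, t in enumerate(order)}
        # canonical contrast = (k, l) with k before l in treatment order
        seen: dict[tuple[str, str], None] = {}
        for o in obs:
            seen.setdefault(self.canonical_pair(o.treat_k, o.treat_l), None)
        self.contrasts = tuple(
            sorted(seen, key=lambda p: (self._index[p[0]], self._index[p[1]]))
        )
        self._contrast_index = {c: i for i, c in enumerate(self.contrasts)}

    # -- bookkeeping -------------------------------------------------------

    def canonical_pair(self, a: str, b: str) -> tuple[str, str]:
        if self._index[a] < self._index[b]:
            return (a, b)
        return (b, a)

    def treatment_index(self, t: str) -> int:
        return self._index[t]

    def contrast_of(self, obs: ContrastObservation) -> tuple[str, str]:
        return self.canonical_pair(obs.treat_k, obs.treat_l)

    @property
    def n_studies(self) -> int:
        return len(self.observations)

    @property
    def n_treatments(self) -> int:
        return len(self.treatments)

    def contrast_indices(self) -> np.ndarray:
        """Index of each observation's contrast in ``self.contrasts``."""
        return np.array(
            [self._contrast_index[self.contrast_of(o)] for o in self.observations]
        )

    def orientation_signs(self) -> np.ndarray:
        """+1 where (treat_k, treat_l) matches the canonical order, else -1."""
        return np.array(
            [
                1.0 if (o.treat_k, o.treat_l) == self.contrast_of(o) else -1.0
                for o in self.observations
            ]
        )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.treatments)
        g.add_edges_from((o.treat_k, o.treat_l) for o in self.observations)
        return g

    # -- derived views -----------------------------------------------------

    def mask_final_outcome(self, study_id: str) -> "NetworkData":
        """Copy with one study's final-outcome estimate set to missing."""
        if all(o.study_id != study_id for o in self.observations):
            raise KeyError(f"no study {study_id!r} in the network")
        new = [
            replace(o, y2=None) if o.study_id == study_id else o
            for o in self.observations
        ]
        return NetworkData(new, self.treatments, self.reference)

    def with_rho_w(self, rho_w: float) -> "NetworkData":
        """Copy applying one within-study correlation to all rows."""
        return NetworkData(
            [replace(o, rho_w=rho_w) for o in self.observations],
            self.treatments,
            self.reference,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "study_id": o.study_id,
                "treat_k": o.treat_k,
                "treat_l": o.treat_l,
                "y1": o.y1,
                "se1": o.se1,
                "y2": o.y2,
                "se2": o.se2,
                "rho_w": o.rho_w,
            }
            for o in self.observations
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, NetworkData)
            and self.observations == other.observations
            and self.treatments == other.treatments
            and self.reference == other.reference
        )

    def __repr__(self) -> str:
        return (
            f"NetworkData({self.n_studies} studies, "
            f"{self.n_treatments} treatments, "
            f"{len(self.contrasts)} contrasts, reference={self.reference!r})"
        )


@dataclass(frozen=True)
class NetworkDiagnostics:
    """Structural summary of a network: study counts and sparse contrasts."""

    n_studies: int
    n_treatments: int
    contrast_counts: Mapping[tuple[str, str], int]
    connected: bool
    components: tuple[tuple[str, ...], ...]
    sparse_contrasts: tuple[tuple[str, str], ...]
    n_missing_final: int


def validate_network(
    data: NetworkData, sparse_threshold: int = 4
) -> NetworkDiagnostics:
    """Report per-contrast study counts, connectivity and sparse contrasts.

    Contrasts with fewer than ``sparse_threshold`` studies are flagged:
    their between-study correlation is largely prior-driven and contrast
    level results are usually not reported for them.  A disconnected
    network (possible when the treatment catalogue contains an isolated
    label) raises :class:`StructuralError`.
    """
    g = data.graph()
    connected = nx.is_connected(g)
    components = tuple(tuple(sorted(c)) for c in nx.connected_components(g))
    if not connected:
        raise StructuralError(
            f"treatment network is disconnected; components: "
            f"{[list(c) for c in components]}"
        )
    counts: dict[tuple[str, str], int] = {c: 0 for c in data.contrasts}
    for o in data.observations:
        counts[data.contrast_of(o)] += 1
    sparse = tuple(c for c, n in counts.items() if n < sparse_threshold)
    return NetworkDiagnostics(
        n_studies=data.n_studies,
        n_treatments=data.n_treatments,
        contrast_counts=counts,
        connected=connected,
        components=components,
        sparse_contrasts=sparse,
        n_missing_final=sum(o.y2_missing for o in data.observations),
    )


def read_contrast_table(
    path,
    sep: str = ",",
    reference: str | None = None,
    rho_w: float | None = None,
) -> NetworkData:
    """Read a delimited contrast-level table into a validated network.

    The file must carry a header with columns ``study_id, treat_k, treat_l,
    y1, se1, y2, se2, rho_w``; empty ``y2`` cells mark missing final-outcome
    estimates.  ``rho_w`` (argument) overrides the per-row within-study
    correlation with a single value, mirroring analyses where one
    IPD-derived correlation is assumed to apply to all studies.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        dtype={"study_id": str, "treat_k": str, "treat_l": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {missing_cols}")
    obs = []
    for idx, row in df.iterrows():
        y2 = row["y2"]
        y2 = None if pd.isna(y2) else float(y2)
        rw = float(rho_w) if rho_w is not None else float(row["rho_w"])
        try:
            obs.append(
                ContrastObservation(
                    study_id=str(row["study_id"]),
                    treat_k=str(row["treat_k"]),
                    treat_l=str(row["treat_l"]),
                    y1=float(row["y1"]),
                    se1=float(row["se1"]),
                    y2=y2,
                    se2=float(row["se2"]),
                    rho_w=rw,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from exc
    return NetworkData(obs, reference=reference)


def write_contrast_table(data: NetworkData, path, sep: str = ",") -> None:
    """Write a network back to delimited text (round-trips bit-identically).

    Floats are written with :func:`repr`, whose shortest-round-trip
    representation reproduces IEEE doubles exactly on re-read.
    """
    df = data.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(sep.join(REQUIRED_COLUMNS) + "\n")
        for _, row in df.iterrows():
            cells = [str(row["study_id"]), str(row["treat_k"]), str(row["treat_l"])]
            for col in ("y1", "se1", "y2", "se2", "rho_w"):
                v = row[col]
                cells.append("" if pd.isna(v) else repr(float(v)))
            fh.write(sep.join(cells) + "\n")
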