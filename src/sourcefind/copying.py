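"""Copying vectors, surrogate profiles and their text I/O.

A *copying vector* summarises a chromosome painting: for one recipient
individual it records the total genome length (in cM) copied from each of
``D`` donor clusters.  Normalised copying vectors of homogeneous reference
("surrogate") clusters act as ancestry profiles; an admixed recipient's
normalised vector is modelled as a convex combination of them.

The on-disk dialect is the whitespace-delimited matrix convention used by
painting pipelines: a header row naming the donor columns, then one row per
recipient (identifier followed by ``D`` numeric lengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DonorPanel",
    "CopyingVector",
    "SurrogateProfile",
    "GroupMapping",
    "AncestryEstimate",
    "ValidationError",
    "ChunklengthsParseError",
    "read_chunklengths",
    "write_chunklengths",
    "read_cluster_members",
    "read_group_mapping",
    "normalize",
    "build_surrogate_profiles",
    "collapse_groups",
    "write_estimates",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class ChunklengthsParseError(ValueError):
    """Raised when a chunklengths file is malformed; names the line."""


@dataclass(frozen=True)
class DonorPanel:
    """Ordered set of donor-cluster identifiers defining vector columns."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValidationError("donor panel must contain at least one cluster")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise ValidationError(f"duplicate donor labels: {dupes}")

    @property
    def size(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.labels)


@dataclass(frozen=True)
class CopyingVector:
    """Per-donor copied genome lengths (cM) for one recipient.

    ``total_c`` is the recipient's painted genome length (both haploid
    genomes), i.e. the row sum of ``lengths``.
    """

    recipient_id: str
    lengths: np.ndarray
    total_c: float

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        if lengths.ndim != 1:
            raise ValidationError("lengths must be a 1-D vector")
        if np.any(lengths < 0):
            raise ValidationError(
                f"negative copying length for recipient {self.recipient_id!r}"
            )
        if self.total_c <= 0:
            raise ValidationError(
                f"recipient {self.recipient_id!r} has non-positive total length"
            )
        if abs(lengths.sum() - self.total_c) > 1e-6 * self.total_c:
            raise ValidationError(
                f"total_c inconsistent with row sum for {self.recipient_id!r}"
            )


@dataclass(frozen=True)
class SurrogateProfile:
    """Normalised average copying vector of one surrogate cluster."""

    surrogate_id: str
    freqs: np.ndarray
    n_individuals: int = 1

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if np.any(freqs < 0):
            raise ValidationError(f"profile {self.surrogate_id!r} has negative entry")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"profile {self.surrogate_id!r} does not sum to 1 (got {freqs.sum()!r})"
            )
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be a positive integer")


@dataclass(frozen=True)
class GroupMapping:
    """Many-to-one map from surrogate clusters to display groups."""

    cluster_to_group: Mapping[str, str]

    def group_of(self, surrogate_id: str) -> str:
        try:
            return self.cluster_to_group[surrogate_id]
        except KeyError:
            raise ValidationError(f"surrogate {surrogate_id!r} has no group") from None


@dataclass
class AncestryEstimate:
    """Final mixture proportions for one recipient with per-run provenance.

    ``per_run`` holds, for each independent MCMC run, the maximum-posterior
    mixture vector and its log posterior; ``combined_weights`` are the
    posterior weights used to average the runs.  NNLS estimates leave both
    empty.
    """

    recipient_id: str
    proportions: dict[str, float]
    per_run: list[tuple[np.ndarray, float]] = field(default_factory=list)
    combined_weights: np.ndarray | None = None

    def as_vector(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.proportions[s] for s in order], dtype=float)


# ---------------------------------------------------------------------------
# I/O


def read_chunklengths(path) -> tuple[DonorPanel, list[CopyingVector]]:
    """Read a whitespace-delimited chunklengths matrix.

    First row: recipient-column token followed by the donor labels.  Each
    subsequent row: recipient id and one non-negative length per donor.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 2:
            raise ChunklengthsParseError(f"{path}: header must name at least one donor")
        panel = DonorPanel(tuple(header[1:]))
        vectors: list[CopyingVector] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != panel.size + 1:
                raise ChunklengthsParseError(
                    f"{path}: line {lineno}: expected {panel.size + 1} fields, "
                    f"got {len(fields)}"
                )
            try:
                row = np.array(fields[1:], dtype=float)
            except ValueError:
                raise ChunklengthsParseError(
                    f"{path}: line {lineno}: non-numeric length field"
                ) from None
            vectors.append(CopyingVector(fields[0], row, float(row.sum())))
    return panel, vectors


def write_chunklengths(path, panel: DonorPanel, vectors: Iterable[CopyingVector]) -> None:
    """Write the same dialect :func:`read_chunklengths` reads."""
    with open(path, "w") as fh:
        fh.write("Recipient " + " ".join(panel.labels) + "\n")
        for cv in vectors:
            if cv.lengths.shape[0] != panel.size:
                raise ValidationError(
                    f"vector {cv.recipient_id!r} has {cv.lengths.shape[0]} entries, "
                    f"panel has {panel.size}"
                )
            fh.write(
                cv.recipient_id + " " + " ".join(repr(float(x)) for x in cv.lengths) + "\n"
            )


def read_cluster_members(path) -> dict[str, list[str]]:
    """Read a two-column TSV (individual_id, surrogate_id) into cluster lists."""
    clusters: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ChunklengthsParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            clusters.setdefault(fields[1], []).append(fields[0])
    return clusters


def read_group_mapping(path) -> GroupMapping:
    """Read a two-column TSV (surrogate_id, group_id)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ChunklengthsParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            if fields[0] in mapping:
                raise ValidationError(f"surrogate {fields[0]!r} mapped twice")
            mapping[fields[0]] = fields[1]
    return GroupMapping(mapping)


def write_estimates(path, estimates: Sequence[AncestryEstimate]) -> None:
    """Write estimates as TSV: recipient_id then one column per surrogate."""
    if not estimates:
        raise ValidationError("no estimates to write")
    order = list(estimates[0].proportions)
    with open(path, "w") as fh:
        fh.write("recipient_id\t" + "\t".join(order) + "\n")
        for est in estimates:
            vals = "\t".join(f"{est.proportions[s]:.6g}" for s in order)
            fh.write(f"{est.recipient_id}\t{vals}\n")


# ---------------------------------------------------------------------------
# Transformations


def normalize(cv: CopyingVector) -> np.ndarray:
    """Return the frequency vector ``lengths / total_c`` (sums to 1)."""
    if cv.total_c <= 0:
        raise ValidationError(f"recipient {cv.recipient_id!r}: degenerate zero total")
    return cv.lengths / cv.total_c


def build_surrogate_profiles(
    cvs_by_cluster: Mapping[str, Sequence[CopyingVector]],
) -> list[SurrogateProfile]:
    """Average the normalised vectors of each cluster's members.

    Averaging is over per-individual *normalised* vectors, not raw lengths,
    so members with different painted totals contribute equally.
    """
    profiles: list[SurrogateProfile] = []
    expected_d: int | None = None
    for surrogate_id, members in cvs_by_cluster.items():
        if len(members) == 0:
            raise ValidationError(f"surrogate cluster {surrogate_id!r} is empty")
        mat = np.vstack([normalize(cv) for cv in members])
        if expected_d is None:
            expected_d = mat.shape[1]
        elif mat.shape[1] != expected_d:
            raise ValidationError(
                f"surrogate cluster {surrogate_id!r} uses a different donor panel"
            )
        mean = mat.mean(axis=0)
        mean = mean / mean.sum()  # guard accumulated rounding
        profiles.append(SurrogateProfile(surrogate_id, mean, len(members)))
    return profiles


def collapse_groups(est: AncestryEstimate, mapping: GroupMapping) -> AncestryEstimate:
    """Sum cluster proportions into display groups; total is conserved."""
    grouped: dict[str, float] = {}
    for surrogate_id, prop in est.proportions.items():
        group = mapping.group_of(surrogate_id)
        grouped[group] = grouped.get(group, 0.0) + prop
    return AncestryEstimate(
        recipient_id=est.recipient_id,
        proportions=grouped,
        per_run=est.per_run,
        combined_weights=est.combined_weights,
    )
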