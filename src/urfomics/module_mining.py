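"""Simpson-index functional similarity and URF-module assembly.

Two features are functionally similar when their enriched-function sets
overlap strongly by the Simpson (overlap) coefficient
``sim = |A ∩ B| / min(|A|, |B|)``.  A non-differential feature whose
Simpson index with some differential feature exceeds the threshold
(strictly, default 0.6) becomes an *auxiliary* feature; the URF-module is
the union of the differential and auxiliary features and is the input
set of the downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["UrfModule", "simpson_index", "find_auxiliary", "build_module"]


def simpson_index(functions_i: set[str], functions_j: set[str]) -> float:
    """Overlap coefficient |i ∩ j| / min(|i|, |j|); in [0, 1]."""
    if not functions_i or not functions_j:
        raise ValueError("no enriched functions")
    inter = len(set(functions_i) & set(functions_j))
    return inter / min(len(functions_i), len(functions_j))


def find_auxiliary(
    differential: dict[str, set[str]],
    all_features: dict[str, set[str]],
    threshold: float = 0.6,
    partner_scores: dict[str, float] | None = None,
) -> list[tuple[str, str, float]]:
    """Identify auxiliary features among the non-differential ones.

    Parameters
    ----------
    differential
        Function sets (enriched terms) of the differential features.
    all_features
        Function sets of all candidate features; differential names are
        skipped, as are features with empty function sets.
    threshold
        Strict lower bound on the Simpson index.
    partner_scores
        Optional score per differential feature (e.g. the sum of its
        enrichment p-values); ties among equally similar partners are
        broken toward the smallest score, then alphabetically.  Affects
        the reported partner only, never membership.

    Returns (auxiliary, best partner, sim) sorted by descending sim.
    """
    out = []
    for name, funcs in all_features.items():
        if name in differential or not funcs:
            continue
        best: tuple[str, float] | None = None
        for diff_name, diff_funcs in differential.items():
            if not diff_funcs:
                continue
            sim = simpson_index(funcs, diff_funcs)
            if best is None or sim > best[1] + 1e-12:
                best = (diff_name, sim)
            elif abs(sim - best[1]) <= 1e-12 and partner_scores is not None:
                if partner_scores.get(diff_name, float("inf")) < partner_scores.get(
                    best[0], float("inf")
                ):
                    best = (diff_name, sim)
        if best is not None and best[1] > threshold:
            out.append((name, best[0], best[1]))
    return sorted(out, key=lambda t: (-t[2], t[0]))


@dataclass(frozen=True)
class UrfModule:
    """Differential features plus Simpson-selected auxiliary features."""

    differential_features: tuple[str, ...]
    auxiliary_features: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        overlap = set(self.differential_features) & set(self.auxiliary_features)
        if overlap:
            raise ValueError(f"auxiliary/differential overlap: {sorted(overlap)}")

    @property
    def features(self) -> tuple[str, ...]:
        return self.differential_features + self.auxiliary_features

    def __len__(self) -> int:
        return len(self.features)


def build_module(
    differential: list[str],
    auxiliary: list[tuple[str, str, float]] | list[str],
) -> UrfModule:
    """Assemble the URF-module with its (auxiliary, partner, sim) edges."""
    if auxiliary and isinstance(auxiliary[0], str):
        aux_names = list(auxiliary)  # type: ignore[arg-type]
        edges: tuple = ()
    else:
        aux_names = [a for a, _, _ in auxiliary]  # type: ignore[misc]
        edges = tuple((a, p, float(s)) for a, p, s in auxiliary)  # type: ignore[misc]
    if len(set(aux_names)) != len(aux_names):
        raise ValueError("duplicate auxiliary features")
    return UrfModule(
        differential_features=tuple(differential),
        auxiliary_features=tuple(aux_names),
        edges=edges,
    )
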