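"""Feature networks: gene-set collections and metabolite-gene neighborhoods.

Both kinds reduce to the same scoring substrate: a mapping from a feature
id (a gene-set name, or a metabolite) to the set of genes it touches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

__all__ = ["FeatureNetwork"]

logger = logging.getLogger(__name__)

KINDS = ("gene_set_collection", "metabolite_bipartite")


@dataclass
class FeatureNetwork:
    """Mapping feature id -> neighbor gene set.

    ``kind`` distinguishes flat gene-set collections (GO / Reactome role)
    from metabolite neighborhoods derived from a metabolic model
    (``metabolite_bipartite``); ``provenance`` is a free-text label for
    reporting.
    """

    features: dict[str, frozenset[str]]
    kind: str = "gene_set_collection"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        self.features = {name: frozenset(members) for name, members in self.features.items()}

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.features

    def __getitem__(self, feature_id: str) -> frozenset[str]:
        return self.features[feature_id]

    def feature_ids(self) -> list[str]:
        return sorted(self.features)

    def resolve(self, universe, min_size: int = 1) -> "FeatureNetwork":
        """Restrict neighbor sets to a gene universe.

        Unresolvable members are dropped (counted and logged); features
        falling below ``min_size`` members are removed.
        """
        universe = frozenset(universe)
        resolved: dict[str, frozenset[str]] = {}
        n_dropped_members = 0
        n_dropped_features = 0
        for name in sorted(self.features):
            members = self.features[name]
            kept = members & universe
            n_dropped_members += len(members) - len(kept)
            if len(kept) >= min_size:
                resolved[name] = kept
            else:
                n_dropped_features += 1
        if n_dropped_members or n_dropped_features:
            logger.info(
                "resolve(%s): dropped %d unresolvable members, %d features below size %d",
                self.provenance or self.kind, n_dropped_members, n_dropped_features, min_size,
            )
        return FeatureNetwork(resolved, kind=self.kind, provenance=self.provenance)
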