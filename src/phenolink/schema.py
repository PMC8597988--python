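"""Phenotype schema: trait names, their closed variant domains, and the SNPs
that inform each trait.

Four face-visible traits are modeled — sex, hair color, skin color and eye
color — each with a small categorical domain. A schema also carries the
``snp_map``: for every trait, the list of rsIDs whose genotypes inform it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence


@dataclass(frozen=True)
class PhenotypeSchema:
    """Closed phenotype domains plus the SNP panel informing each phenotype.

    Parameters
    ----------
    phenotypes
        Ordered phenotype names.
    variant_domain
        Phenotype name -> ordered tuple of variant labels.
    snp_map
        Phenotype name -> tuple of rsID strings (the relevant SNPs).
    """

    phenotypes: tuple[str, ...]
    variant_domain: Mapping[str, tuple[str, ...]]
    snp_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for p in self.phenotypes:
            dom = self.variant_domain.get(p)
            if not dom:
                raise ValueError(f"phenotype {p!r} has an empty variant domain")
            if len(set(dom)) != len(dom):
                raise ValueError(f"phenotype {p!r} has duplicate variants: {dom}")
        extra = set(self.variant_domain) - set(self.phenotypes)
        if extra:
            raise ValueError(f"variant_domain has unknown phenotypes: {sorted(extra)}")
        for p in self.snp_map:
            if p not in self.phenotypes:
                raise ValueError(f"snp_map references unknown phenotype {p!r}")

    @property
    def all_snps(self) -> tuple[str, ...]:
        """All rsIDs in the panel, deduplicated, in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.phenotypes:
            for rsid in self.snp_map.get(p, ()):
                seen.setdefault(rsid, None)
        return tuple(seen)

    def domain(self, phenotype: str) -> tuple[str, ...]:
        if phenotype not in self.variant_domain:
            raise KeyError(f"unknown phenotype {phenotype!r}")
        return tuple(self.variant_domain[phenotype])

    def variant_index(self, phenotype: str, variant: str) -> int:
        dom = self.domain(phenotype)
        try:
            return dom.index(variant)
        except ValueError:
            raise ValueError(
                f"variant {variant!r} not in domain {dom} of phenotype {phenotype!r}"
            ) from None

    def relevant_snps(self, phenotype: str) -> tuple[str, ...]:
        return tuple(self.snp_map.get(phenotype, ()))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "phenotypes": list(self.phenotypes),
            "variant_domain": {p: list(v) for p, v in self.variant_domain.items()},
            "snp_map": {p: list(v) for p, v in self.snp_map.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhenotypeSchema":
        payload = json.loads(Path(path).read_text())
        return cls(
            phenotypes=tuple(payload["phenotypes"]),
            variant_domain={p: tuple(v) for p, v in payload["variant_domain"].items()},
            snp_map={p: tuple(v) for p, v in payload.get("snp_map", {}).items()},
        )


#: Standard domains for the four face-visible traits.
DEFAULT_DOMAINS: dict[str, tuple[str, ...]] = {
    "sex": ("F", "M"),
    "hair": ("black", "blonde", "brown"),
    "skin": ("pale", "intermediate", "dark"),
    "eye": ("blue", "brown", "intermediate"),
}

#: Synthetic biallelic SNP panel: 2-4 informative SNPs per trait. The rsIDs are
#: placeholders for a user-supplied panel; real analyses pass their own snp_map.
DEFAULT_SNP_MAP: dict[str, tuple[str, ...]] = {
    "sex": ("rs9001", "rs9002"),
    "hair": ("rs9003", "rs9004", "rs9005"),
    "skin": ("rs9006", "rs9007", "rs9008"),
    "eye": ("rs9009", "rs9010", "rs9011", "rs9012"),
}


def default_schema(snp_map: Mapping[str, Sequence[str]] | None = None) -> PhenotypeSchema:
    """The four-trait schema with standard domains.

    ``snp_map`` overrides the synthetic default panel; pass the panel actually
    genotyped in your cohort.
    """
    if snp_map is None:
        snp_map = DEFAULT_SNP_MAP
    return PhenotypeSchema(
        phenotypes=("sex", "hair", "skin", "eye"),
        variant_domain=dict(DEFAULT_DOMAINS),
        snp_map={p: tuple(v) for p, v in snp_map.items()},
    )
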