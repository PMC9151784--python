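"""End-to-end HGT pipeline: alien-index screen -> microsynteny confirmation."""

from __future__ import annotations

from dataclasses import dataclass, field

from .alien import AlienIndexRecord, build_records, screen_candidates
from .io import GenomeAnnotation, HomologyHit, OrthogroupMap
from .microsynteny import HGTCall, call_hgt_events
from .simulate import SyntheticBundle

__all__ = ["PipelineResult", "screen_species", "run_hgt_pipeline"]


@dataclass
class PipelineResult:
    candidates: dict[str, list[AlienIndexRecord]]
    calls: list[HGTCall] = field(default_factory=list)

    @property
    def confident(self) -> list[HGTCall]:
        return [c for c in self.calls if c.confident]


def screen_species(hits_by_species: dict[str, list[HomologyHit]],
                   skip_taxa: set[str] = frozenset(),
                   ai_threshold: float = 0.0) -> dict[str, list[AlienIndexRecord]]:
    """Alien-index screen per species; returns candidate lists."""
    return {sp: screen_candidates(build_records(hits_by_species[sp], skip_taxa,
                                                ai_threshold), ai_threshold)
            for sp in sorted(hits_by_species)}


def run_hgt_pipeline(annotations: dict[str, GenomeAnnotation] | SyntheticBundle,
                     hits: dict[str, list[HomologyHit]] | None = None,
                     orthomap: OrthogroupMap | None = None,
                     ai_threshold: float = 0.0,
                     skip_taxa: set[str] = frozenset(),
                     min_species: int = 3,
                     min_shared: int = 2,
                     flank_width: int = 5) -> PipelineResult:
    """Run screen + microsynteny confirmation on a bundle or raw inputs."""
    if isinstance(annotations, SyntheticBundle):
        bundle = annotations
        annotations, hits, orthomap = bundle.annotations, bundle.hits, bundle.orthomap
    if hits is None or orthomap is None:
        raise ValueError("hits and orthomap are required with raw annotations")
    candidates = screen_species(hits, skip_taxa, ai_threshold)
    calls = call_hgt_events(candidates, annotations, orthomap,
                            min_species=min_species, min_shared=min_shared,
                            flank_width=flank_width)
    return PipelineResult(candidates, calls)
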