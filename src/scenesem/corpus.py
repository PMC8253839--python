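"""Annotation corpora of scenes.

A corpus is an ordered collection of *scenes*, each a deduplicated set of
object labels, mirroring how densely annotated image datasets (one label per
visible object, repeats collapsed) are converted into a bag-of-words training
corpus. Labels may contain spaces; scenes are stored one per line with
tab-separated labels.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import InvalidMapError, MalformedLabelError

__all__ = [
    "AnnotationCorpus",
    "LabelMap",
    "scene_from_tokens",
    "canonical_first_name",
    "harmonize",
    "read_corpus",
    "write_corpus",
    "read_label_map",
]


def scene_from_tokens(tokens: Sequence[str]) -> tuple[str, ...]:
    """Deduplicate a token list into a scene, preserving first-occurrence order.

    Repeated occurrences of an object in one image carry no extra information
    for co-occurrence modelling, so a scene is the *set* of labels present.
    """
    if not tokens:
        raise MalformedLabelError("a scene requires at least one label")
    seen: dict[str, None] = {}
    for tok in tokens:
        if not isinstance(tok, str) or not tok.strip():
            raise MalformedLabelError(f"empty or blank label in scene: {tokens!r}")
        seen.setdefault(tok, None)
    return tuple(seen)


def canonical_first_name(label_list_string: str) -> str:
    """Reduce a comma-separated list of synonymous names to its first entry.

    Annotation datasets often attach several names to one object class
    (e.g. ``"bathtub, bathing tub, bath, tub"``); the first name is taken as
    canonical.
    """
    if not isinstance(label_list_string, str) or not label_list_string.strip():
        raise MalformedLabelError("empty name list")
    first = label_list_string.split(",")[0].strip()
    if not first:
        raise MalformedLabelError(f"name list starts with an empty name: {label_list_string!r}")
    return first


@dataclass(frozen=True)
class LabelMap:
    """Mapping from variant labels to canonical labels.

    The mapping must be idempotent after one application: a canonical label
    either maps to itself or does not appear as a key.
    """

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for variant, canon in self.mapping.items():
            target = self.mapping.get(canon, canon)
            if target != canon:
                raise InvalidMapError(
                    f"map is not idempotent: {variant!r} -> {canon!r} -> {target!r}"
                )

    def apply(self, label: str) -> str:
        return self.mapping.get(label, label)

    @classmethod
    def identity(cls) -> "LabelMap":
        return cls({})


@dataclass
class AnnotationCorpus:
    """Ordered scenes plus a vocabulary of scenes-containing counts."""

    scenes: list[tuple[str, ...]]
    vocabulary: Counter = field(init=False)

    def __post_init__(self) -> None:
        self.scenes = [scene_from_tokens(s) for s in self.scenes]
        self.vocabulary = Counter()
        for scene in self.scenes:
            self.vocabulary.update(scene)

    def __len__(self) -> int:
        return len(self.scenes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationCorpus):
            return NotImplemented
        return self.scenes == other.scenes

    @classmethod
    def from_scenes(cls, scenes: Iterable[Sequence[str]]) -> "AnnotationCorpus":
        return cls(list(scenes))


def harmonize(corpus: AnnotationCorpus, label_map: LabelMap) -> AnnotationCorpus:
    """Replace every variant label by its canonical form and re-deduplicate.

    Two variants of the same object in one scene collapse to a single label.
    """
    return AnnotationCorpus(
        [scene_from_tokens([label_map.apply(lbl) for lbl in scene]) for scene in corpus.scenes]
    )


def read_corpus(path: str | Path) -> AnnotationCorpus:
    """Read a corpus from UTF-8 text: one scene per line, tab-separated labels."""
    scenes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                warnings.warn(f"{path}: blank line {lineno} skipped", stacklevel=2)
                continue
            scenes.append(scene_from_tokens(line.split("\t")))
    return AnnotationCorpus(scenes)


def write_corpus(corpus: AnnotationCorpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for scene in corpus.scenes:
            fh.write("\t".join(scene) + "\n")


def read_label_map(path: str | Path) -> LabelMap:
    """Read a two-column tab-separated (variant, canonical) label map."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InvalidMapError(f"{path}:{lineno}: expected 2 tab-separated columns")
            mapping[parts[0]] = parts[1]
    return LabelMap(mapping)
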