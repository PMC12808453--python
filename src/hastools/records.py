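"""Core record container shared across modules.

A :class:`ProteinRecord` is a protein sequence plus the identifiers the pipeline
threads through every stage: the assembly it came from, an optional taxonomy
triple, free-form annotation labels (a fusion protein carries two family
labels), and — for synthetic corpora — the planted truth type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: separator used when one gene carries several family labels (fusions)
LABEL_SEP = ";"


@dataclass
class ProteinRecord:
    id: str
    seq: str
    description: str = ""
    assembly: str | None = None
    taxonomy: tuple[str, str, str] | None = None  # (domain, phylum, class)
    labels: tuple[str, ...] = field(default_factory=tuple)
    truth_type: str | None = None

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def annotation(self) -> str:
        return LABEL_SEP.join(self.labels)


def split_labels(annotation: str) -> list[str]:
    """Split a (possibly multi-label) annotation string into its family labels."""
    return [p for p in annotation.split(LABEL_SEP) if p]
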