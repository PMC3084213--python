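import io
import textwrap

import pytest

from cincat.catalogue import GeneMeta, ScreenHit, integrate_screens
from cincat.ontology import AnnotationSet, OntologyDAG, OntologyTerm


def tsv(text: str) -> io.StringIO:
    """Dedent a triple-quoted TSV literal into a stream."""
    return io.StringIO(textwrap.dedent(text).lstrip("\n"))


@pytest.fixture
def chain_dag() -> OntologyDAG:
    # c is_a b is_a a
    return OntologyDAG(
        [
            OntologyTerm("a", name="root"),
            OntologyTerm("b", parents=(("a", "is_a"),)),
            OntologyTerm("c", parents=(("b", "is_a"),)),
        ]
    )


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    # d -> b -> a and d -> c -> a
    return OntologyDAG(
        [
            OntologyTerm("a", name="root"),
            OntologyTerm("b", parents=(("a", "is_a"),)),
            OntologyTerm("c", parents=(("a", "part_of"),)),
            OntologyTerm("d", parents=(("b", "is_a"), ("c", "part_of"))),
        ]
    )


@pytest.fixture
def small_catalogue():
    hits_a = [
        ScreenHit("Y1", "CTF", "STRONG", "studyA"),
        ScreenHit("Y2", "CTF", "WEAK", "studyA"),
    ]
    hits_b = [
        ScreenHit("Y1", "GCR", "WEAK", "studyB"),
        ScreenHit("Y3", "ALF", "WEAK", "studyB"),
    ]
    meta = [
        GeneMeta("Y1", essential=True, nuclear=True),
        GeneMeta("Y2", essential=False, nuclear=False),
        GeneMeta("Y3", essential=False, nuclear=True),
    ]
    return integrate_screens([hits_a, hits_b], meta)


def make_annotations(**gene_terms) -> AnnotationSet:
    return AnnotationSet(
        mapping={g: set(t) for g, t in gene_terms.items()}, closed=False
    )
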