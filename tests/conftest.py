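"""Shared fixtures: the packaged BARD1 resources, a toy transcript model,
and an independent brute-force NMD oracle used to cross-check the
package's heuristic and sequence-aware predictions."""

from __future__ import annotations

import io

import pytest
from Bio.Seq import Seq

from bardsplice import (
    bard1_catalogue, bard1_domains, bard1_model, bard1_site_rules,
)
from bardsplice.catalogue import load_catalogue
from bardsplice.events import Deletion
from bardsplice.transcript import (
    DomainInterval, DomainMap, Exon, TranscriptModel,
)


@pytest.fixture(scope="session")
def model():
    return bard1_model()


@pytest.fixture(scope="session")
def domains():
    return bard1_domains("exon")


@pytest.fixture(scope="session")
def codon_domains():
    return bard1_domains("codon")


@pytest.fixture(scope="session")
def catalogue():
    return bard1_catalogue()


@pytest.fixture(scope="session")
def site_rules():
    return bard1_site_rules()


# -- toy gene for constructed scenarios -----------------------------------


@pytest.fixture(scope="session")
def toy_model():
    """5-exon synthetic gene; exon 3 (90 nt, codon multiple) carries no
    domain, so its skip is a potential rescue transcript."""
    exons = (Exon(1, 1, 60), Exon(2, 61, 150), Exon(3, 151, 240),
             Exon(4, 241, 330), Exon(5, 331, 405))
    return TranscriptModel(exons=exons, cds_end=405, protein_length=134)


@pytest.fixture(scope="session")
def toy_domains():
    return DomainMap(domains=(DomainInterval("D1", 2, 2),
                              DomainInterval("D2", 4, 5)), level="exon")


@pytest.fixture(scope="session")
def toy_rescue_catalogue():
    """Synthetic catalogue whose only entry is an in-frame,
    domain-preserving skip of exon 3 (a rescue transcript)."""
    tsv = ("event_code\tr_description\tfunctional\tnovel\tRP|labX|LCL\n"
           "Full length\t-\tIF\tno\t+\n"
           "Δ(E3)\tr.151_240del\tIF\tno\t+\n")
    return load_catalogue(io.StringIO(tsv))


# -- independent NMD oracle ------------------------------------------------


def brute_force_nmd(sequence: str, deletions, model, window: int = 50):
    """Translate the altered transcript with Biopython and apply the 50-nt
    rule directly; independent of the package's NMD code path.

    ``deletions`` is a list of (start, end) c. intervals.  Returns
    (call, ptc_exon) with call in {'NMD_predicted', 'NMD_escape'}.
    """
    dels = sorted(deletions)
    keep = []
    cursor = 1
    for s, e in dels:
        keep.append((cursor, s - 1))
        cursor = e + 1
    keep.append((cursor, model.cds_end))
    ref_pos = [p for a, b in keep for p in range(a, b + 1)]
    altered = "".join(sequence[p - 1] for p in ref_pos)

    protein = str(Seq(altered[: 3 * (len(altered) // 3)]).translate())
    stop_idx = protein.find("*")

    # junction positions in altered coordinates, computed independently
    # from the boundary table
    deleted = set()
    for s, e in dels:
        deleted.update(range(s, e + 1))
    alt_of = {p: i + 1 for i, p in enumerate(ref_pos)}
    junctions = []
    for don, acc in model.natural_junctions():
        if don in deleted or acc in deleted:
            continue
        junctions.append(alt_of[don])
    for s, e in dels:
        if s - 1 >= 1 and (s - 1) not in deleted:
            junctions.append(alt_of[s - 1])
    last_junction = max(junctions)

    if stop_idx < 0:
        return "NMD_escape", None
    stop_last_nt = 3 * (stop_idx + 1)
    ptc_exon = model.exon_of_position(ref_pos[3 * stop_idx]).index
    if last_junction - stop_last_nt > window:
        return "NMD_predicted", ptc_exon
    return "NMD_escape", ptc_exon
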