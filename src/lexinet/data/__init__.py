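"""Bundled demonstration wordlists (small, synthetic, plain TSV).

All four datasets were hand-assembled for this package from well-known
lexical material; they are synthetic stand-ins for research datasets, sized
for tests and worked examples.
"""

from importlib import resources

from ..lexio import Wordlist, read_wordlist

__all__ = ["person_wordlist", "face_wordlist", "moon_wordlist",
           "compound_wordlist", "data_path"]


def data_path(name: str):
    """Filesystem path of a bundled data file."""
    return resources.files(__package__) / name


def _load(name: str) -> Wordlist:
    with resources.as_file(data_path(name)) as path:
        return read_wordlist(path)


def person_wordlist() -> Wordlist:
    """'person' in Germanic/Romance/Slavic (synthetic): five large cognate
    clusters, one of them dominated by Romance reflexes of Latin *persona*
    with borrowed Germanic and Slavic members."""
    return _load("person_synthetic.tsv")


def face_wordlist() -> Wordlist:
    """'face' in 20 Chinese dialect varieties (synthetic): liǎn-type and
    miàn-type words plus one fused liǎn-miàn form acting as a network hub."""
    return _load("face_synthetic.tsv")


def moon_wordlist() -> Wordlist:
    """Mandarin vs Cantonese 'moon' (synthetic fixture tokens): partially
    cognate bimorphemic words."""
    return _load("moon_synthetic.tsv")


def compound_wordlist() -> Wordlist:
    """German Krankheitsverlauf word family (synthetic): compound detection
    demo."""
    return _load("compound_synthetic.tsv")
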