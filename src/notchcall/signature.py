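"""Packaged default NOTCH activation signature.

The up-set holds 21 NOTCH target genes whose expression is expected to be
higher in NOTCH-activated tumors; the down-set holds four genes (LXN,
RAPGEF3, TMEM154, LGR6) expected to be lower.  Both ship as a GMT file that
users can replace with their own curation.
"""

from __future__ import annotations

from importlib import resources

from .io_formats import GeneSignature, read_gmt

__all__ = ["default_signature", "load_signature_gmt"]


def load_signature_gmt(path) -> GeneSignature:
    """Build a GeneSignature from a two-set GMT (``*_UP`` and ``*_DOWN``)."""
    sets = {s.name: s for s in read_gmt(path)}
    up = next((s for n, s in sets.items() if n.endswith("_UP")), None)
    down = next((s for n, s in sets.items() if n.endswith("_DOWN")), None)
    if up is None or down is None:
        raise ValueError(
            "signature GMT must contain one set named *_UP and one named *_DOWN"
        )
    base = up.name[: -len("_UP")]
    return GeneSignature(name=base, up_genes=list(up.genes), down_genes=list(down.genes))


def default_signature() -> GeneSignature:
    """The packaged 21-gene up / 4-gene down NOTCH signature."""
    ref = resources.files("notchcall.data").joinpath("notch_signature.gmt")
    with resources.as_file(ref) as path:
        return load_signature_gmt(path)
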