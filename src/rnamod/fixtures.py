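"""Bundled yeast-like rRNA fixture (synthetic stand-in).

The annotation carries 37 sites on 18S and 73 on 25S.  Positions named in
published text (e.g. the 25S peptidyl-transfer-center run 2921/2922/2923 and
the U24-guided triad 1437/1449/1450) appear at their real coordinates with
their real guides; the remaining positions and the reference sequence itself
are synthetic, generated deterministically, so the fixture exercises the real
annotation geometry without shipping third-party data.
"""

from __future__ import annotations

from importlib import resources

from .model_space import ModificationSite, load_annotation, load_reference


def fixture_path(name: str):
    return resources.files("rnamod.data").joinpath(name)


def yeast_reference() -> dict[str, str]:
    with resources.as_file(fixture_path("yeast_rrna_synthetic.fa")) as p:
        return load_reference(p)


def yeast_annotation() -> tuple[list[ModificationSite], dict[str, str]]:
    """(sites, reference) for the bundled synthetic yeast-like fixture."""
    reference = yeast_reference()
    with resources.as_file(fixture_path("yeast_rrna_synthetic_sites.tsv")) as p:
        sites = load_annotation(p, reference)
    return sites, reference
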