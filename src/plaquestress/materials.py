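"""Default material parameter sets for wall layers and plaque components.

Values are biaxial/uniaxial fits for carotid tissue (kPa); the media is
available both as a fiber-reinforced anisotropic layer and as an isotropic
3rd-order Yeoh fit of the same biaxial response.  Lipid core and fibrous
tissue each come in a "soft" and "hard" variant spanning the experimentally
reported stiffness range; these two extremes are the limits of the
corresponding screening factors.
"""

from __future__ import annotations

from .constitutive import ConstitutiveModel, MediaAnisoParams, YeohParams

MEDIA_ANISO = MediaAnisoParams(mu=122.3, k1=24.7, k2=16.5, phi_deg=6.9, rho=0.8)
MEDIA_ISO = YeohParams(c10=122.3, c20=0.0, c30=337.7, order=3)
ADVENTITIA = YeohParams(c10=88.7, c20=0.0, c30=45301.4, order=3)
LIPID_CORE_SOFT = YeohParams(c10=0.1, order=1)
LIPID_CORE_HARD = YeohParams(c10=50.0, order=1)
FT_C20 = 20.0  # fixed strain-stiffening constant of the fibrous tissue
FIBROUS_TISSUE_SOFT = YeohParams(c10=2.7, c20=FT_C20, order=2)
FIBROUS_TISSUE_HARD = YeohParams(c10=342.1, c20=FT_C20, order=2)

MATERIALS: dict[str, ConstitutiveModel] = {
    "media_anisotropic": MEDIA_ANISO,
    "media_isotropic": MEDIA_ISO,
    "adventitia": ADVENTITIA,
    "lipid_core_soft": LIPID_CORE_SOFT,
    "lipid_core_hard": LIPID_CORE_HARD,
    "fibrous_tissue_soft": FIBROUS_TISSUE_SOFT,
    "fibrous_tissue_hard": FIBROUS_TISSUE_HARD,
}


def lipid_core(c10: float) -> YeohParams:
    """Neo-Hookean lipid core at the given initial stiffness [kPa]."""
    return YeohParams(c10=float(c10), order=1)


def fibrous_tissue(c10: float, c20: float = FT_C20) -> YeohParams:
    """2nd-order Yeoh fibrous tissue at the given initial stiffness [kPa]."""
    return YeohParams(c10=float(c10), c20=float(c20), order=2)


def from_dict(d: dict) -> ConstitutiveModel:
    """Build a model from a config mapping (field names as in the tables).

    Yeoh entries use c10/c20/c30 (+ optional order); anisotropic media uses
    mu, k1, k2, phi (degrees) and rho.
    """
    d = dict(d)
    if "mu" in d:
        return MediaAnisoParams(mu=d["mu"], k1=d["k1"], k2=d["k2"],
                                phi_deg=d.get("phi", d.get("phi_deg")), rho=d["rho"])
    order = d.pop("order", None)
    c10, c20, c30 = d.get("c10"), d.get("c20", 0.0), d.get("c30", 0.0)
    if order is None:
        order = 3 if c30 else (2 if c20 else 1)
    return YeohParams(c10=c10, c20=c20, c30=c30, order=order)


def load_materials(path) -> dict[str, ConstitutiveModel]:
    """Read a YAML/JSON material table keyed by tissue name."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {name: from_dict(entry) for name, entry in raw.items()}


def media(behaviour: str) -> ConstitutiveModel:
    """Media model by behaviour: 'isotropic' or 'anisotropic'."""
    if behaviour == "isotropic":
        return MEDIA_ISO
    if behaviour == "anisotropic":
        return MEDIA_ANISO
    raise ValueError(f"unknown media behaviour {behaviour!r}")
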