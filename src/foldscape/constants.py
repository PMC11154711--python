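"""Physical constants and package-wide defaults (SI unless noted)."""

#: Boltzmann constant, J/K
KB = 1.380649e-23

#: Gas constant in kcal/(mol·K) — thermodynamic fits work in kcal/mol
R_KCAL = 1.987e-3

#: Room temperature, K
ROOM_TEMPERATURE = 298.15

#: Viscosity of water at 25 °C, Pa·s
WATER_VISCOSITY = 0.89e-3

#: Default confocal-volume aspect ratio l/r (axial half-length over lateral radius)
DEFAULT_ASPECT_RATIO = 5.0

#: Diffusion coefficient of rhodamine-6G in water, m²/s (4.14e-6 cm²/s)
RH6G_DIFFUSION = 4.14e-10


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - 273.15
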