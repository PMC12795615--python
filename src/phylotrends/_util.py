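"""Small shared helpers: rounding, distances, seed derivation."""

from __future__ import annotations

import zlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

EARTH_RADIUS_KM = 6371.0


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round to `ndigits` decimals with ties going away from zero.

    Operates on the shortest decimal representation of the float (``repr``),
    so a value written as ``10.005`` in a table rounds to ``10.01`` even
    though its binary double sits fractionally below the tie.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def centideg(x: float) -> int:
    """Coordinate key as integer hundredths of a degree (exact join key)."""
    return int(round(round_half_away(x, 2) * 100))


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between coordinate arrays (degrees)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine(lats, lons) -> np.ndarray:
    """Symmetric great-circle distance matrix (km) for point arrays."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    return haversine_km(lats[:, None], lons[:, None], lats[None, :], lons[None, :])


def derive_seed(root_seed: int, *keys) -> int:
    """Deterministic sub-seed (< 2**31) for a named stage or item index.

    One root seed governs every stochastic stage; sub-streams are derived
    through ``SeedSequence`` spawn keys so serial and parallel execution of
    per-assemblage work agree.
    """
    spawn_key = tuple(
        zlib.crc32(k.encode("utf-8")) if isinstance(k, str) else int(k) for k in keys
    )
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=spawn_key)
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(root_seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root_seed, *keys))
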