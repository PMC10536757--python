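"""Swappable street-level image sources.

All remote access lives behind this module. The default source reads a
fixture directory laid out as ``<root>/<point_id>_<heading>.png``; the API
client is a documented stub for the static street-view endpoint (paid and
rate-limited, so it is opt-in, never exercised by tests) with an on-disk
cache mirroring the fixture layout so repeat fetches make zero remote calls.
A missing image is a normal outcome (it feeds point exclusion), not an
error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

from .sampler import ImageRequest


@dataclass
class ImageSourceConfig:
    mode: str = "fixtures"  # fixtures | api
    root: Optional[Path] = None
    endpoint: str = "https://maps.googleapis.com/maps/api/streetview"
    api_key: Optional[str] = None
    cache_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.mode == "fixtures":
            if self.root is None or not Path(self.root).is_dir():
                raise ValueError("fixtures mode requires an existing root directory")
        elif self.mode == "api":
            if not self.api_key:
                raise ValueError("api mode requires an api_key")
        else:
            raise ValueError(f"unknown image source mode {self.mode!r}")


def _filename(request: ImageRequest) -> str:
    return f"{request.point_id}_{request.heading_deg}.png"


class FixtureImageSource:
    """Serve images from a local directory; absent file => missing."""

    def __init__(self, root) -> None:
        self.root = Path(root)
        self.reads = 0

    def get(self, request: ImageRequest) -> Optional[bytes]:
        path = self.root / _filename(request)
        if not path.is_file():
            return None
        self.reads += 1
        return path.read_bytes()


class ApiImageSource:
    """Static street-view API client stub with an idempotent cache.

    ``transport`` is the injectable HTTP layer: a callable taking a URL and
    returning image bytes or None. The default transport refuses to run, so
    no code path in this package performs network access unless a deployment
    supplies one explicitly.
    """

    def __init__(
        self,
        config: ImageSourceConfig,
        transport: Optional[Callable[[str], Optional[bytes]]] = None,
    ) -> None:
        self.config = config
        self.transport = transport
        self.remote_calls = 0
        self.cache_dir = Path(config.cache_dir or "streetview_cache")
        self.cache_dir.mkdir(parents=True, exist_ok=True)

    def _url(self, request: ImageRequest) -> str:
        return (
            f"{self.config.endpoint}?size=640x640"
            f"&location={request.lat:.7f},{request.lon:.7f}"
            f"&heading={request.heading_deg}&key={self.config.api_key}"
        )

    def get(self, request: ImageRequest) -> Optional[bytes]:
        cached = self.cache_dir / _filename(request)
        if cached.is_file():
            return cached.read_bytes()
        if self.transport is None:
            raise RuntimeError(
                "no transport configured: refusing implicit network access"
            )
        self.remote_calls += 1
        try:
            data = self.transport(self._url(request))
        except Exception as exc:  # surface with request context
            raise RuntimeError(
                f"fetch failed for point {request.point_id} "
                f"heading {request.heading_deg}: {exc}"
            ) from exc
        if data is None:
            return None
        cached.write_bytes(data)
        return data


def make_source(config: ImageSourceConfig, transport=None):
    if config.mode == "fixtures":
        return FixtureImageSource(config.root)
    return ApiImageSource(config, transport=transport)


def fetch(request: ImageRequest, source) -> Optional[bytes]:
    """Fetch one image; updates the request status in place."""
    data = source.get(request)
    request.status = "fetched" if data is not None else "missing"
    return data


def fetch_all(requests, source) -> list[ImageRequest]:
    for req in requests:
        fetch(req, source)
    return list(requests)
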