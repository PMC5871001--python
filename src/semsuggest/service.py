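"""HTTP query-suggestion service.

A minimal WSGI application exposing

    GET /api/v1/semanticsuggestion/<url-encoded query>

which returns ``{"suggestions": [...]}`` — the top-k (default 5)
alternative queries for the decoded query, phrase tokens rendered with
spaces. The model is loaded once at startup; each request is stateless.
"""

from __future__ import annotations

import json
import logging
import time
from typing import Callable, Iterable
from urllib.parse import unquote

from .corpus import PHRASE_DELIMITER
from .suggest import OutOfVocabularyError, top_k
from .train import EmbeddingModel

__all__ = ["create_app", "serve", "ROUTE_PREFIX"]

ROUTE_PREFIX = "/api/v1/semanticsuggestion/"

logger = logging.getLogger(__name__)


def _json_response(
    start_response: Callable, status: str, payload: dict
) -> list[bytes]:
    body = json.dumps(payload, ensure_ascii=False).encode("utf-8")
    start_response(
        status,
        [
            ("Content-Type", "application/json; charset=utf-8"),
            ("Content-Length", str(len(body))),
        ],
    )
    return [body]


def create_app(
    model: EmbeddingModel | None, k: int = 5
) -> Callable[[dict, Callable], Iterable[bytes]]:
    """Build the WSGI application serving suggestions from ``model``.

    Contract: HTTP 200 with {"suggestions": [<= k strings]}; empty list for
    fully out-of-vocabulary queries; 400 for an empty query; 404 off the
    route; 405 for non-GET; 503 when no model is loaded.
    """

    def app(environ: dict, start_response: Callable) -> Iterable[bytes]:
        started = time.monotonic()
        path = environ.get("PATH_INFO", "")
        method = environ.get("REQUEST_METHOD", "GET")
        if method != "GET":
            return _json_response(
                start_response, "405 Method Not Allowed",
                {"error": "only GET is supported"},
            )
        if not path.startswith(ROUTE_PREFIX):
            return _json_response(
                start_response, "404 Not Found", {"error": "unknown route"}
            )
        if model is None:
            return _json_response(
                start_response, "503 Service Unavailable",
                {"error": "model not loaded"},
            )
        query = unquote(path[len(ROUTE_PREFIX):]).strip()
        if not query:
            return _json_response(
                start_response, "400 Bad Request", {"error": "empty query"}
            )
        try:
            suggestions = [
                term.replace(PHRASE_DELIMITER, " ")
                for term, _ in top_k(model, query, k=k)
            ]
        except OutOfVocabularyError:
            suggestions = []
        logger.info(
            "query=%r latency_ms=%.1f results=%d",
            query, 1e3 * (time.monotonic() - started), len(suggestions),
        )
        return _json_response(
            start_response, "200 OK", {"suggestions": suggestions}
        )

    return app


def serve(
    model_path: str, host: str = "127.0.0.1", port: int = 8080, k: int = 5
) -> None:
    """Load a model and serve suggestions until interrupted (wsgiref)."""
    from wsgiref.simple_server import make_server

    from .suggest import load_model

    model = load_model(model_path)
    app = create_app(model, k=k)
    with make_server(host, port, app) as httpd:
        logger.info("serving %d-word model on http://%s:%d%s<query>",
                    len(model), host, port, ROUTE_PREFIX)
        httpd.serve_forever()
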