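"""Minimal HTTP wrapper around the CDS Hooks service layer.

Serves ``GET /cds-services`` (discovery) and
``POST /cds-services/<service-id>`` (invoke) using the standard-library
HTTP server.  Intended for local experimentation and the CLI
``serve-cds`` command; not a production deployment.
"""

from __future__ import annotations

import json
from http.server import BaseHTTPRequestHandler, HTTPServer
from typing import Optional

from dmpkit.hooks import (
    InvalidRequestError,
    UnknownServiceError,
    cds_discovery,
    invoke_service,
)
from dmpkit.registry import ModuleRegistry, builtin_defaults


def make_handler(registry: ModuleRegistry):
    class CdsHandler(BaseHTTPRequestHandler):
        def _send(self, status: int, payload: dict) -> None:
            body = json.dumps(payload).encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def do_GET(self) -> None:  # noqa: N802 (http.server API)
            if self.path.rstrip("/") == "/cds-services":
                self._send(200, cds_discovery())
            else:
                self._send(404, {"error": "not found"})

        def do_POST(self) -> None:  # noqa: N802
            if not self.path.startswith("/cds-services/"):
                self._send(404, {"error": "not found"})
                return
            service_id = self.path.rsplit("/", 1)[-1]
            length = int(self.headers.get("Content-Length", 0))
            try:
                request = json.loads(self.rfile.read(length) or b"{}")
            except json.JSONDecodeError:
                self._send(400, {"error": "request body is not valid JSON"})
                return
            try:
                self._send(200, invoke_service(service_id, request, registry))
            except UnknownServiceError:
                self._send(404, {"error": f"unknown service {service_id!r}"})
            except InvalidRequestError as exc:
                self._send(400, {"error": str(exc), "problems": exc.problems})

        def log_message(self, fmt: str, *args) -> None:  # quiet by default
            pass

    return CdsHandler


def build_server(port: int = 8080,
                 registry: Optional[ModuleRegistry] = None) -> HTTPServer:
    """Construct the HTTP server without starting it (port 0 picks a free
    port; the bound port is in ``server.server_address``)."""
    registry = registry or builtin_defaults()
    return HTTPServer(("127.0.0.1", port), make_handler(registry))


def serve(port: int = 8080, registry: Optional[ModuleRegistry] = None,
          max_requests: Optional[int] = None) -> None:
    """Run the CDS Hooks HTTP server (blocking).

    `max_requests` bounds the number of handled requests (useful in
    tests); None serves forever.
    """
    server = build_server(port, registry)
    try:
        if max_requests is None:
            server.serve_forever()
        else:
            for _ in range(max_requests):
                server.handle_request()
    finally:
        server.server_close()
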