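"""Structured logging used by every pipeline stage.

Each stage logs through ``stage_logger(name)``; records carry the stage tag
and an optional counts payload so batch runs leave an auditable trail.
"""
from __future__ import annotations

import logging

_FORMAT = "%(levelname)s [%(name)s] %(message)s"


def stage_logger(stage: str) -> logging.Logger:
    logger = logging.getLogger(f"qsprkit.{stage}")
    if not logging.getLogger("qsprkit").handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_FORMAT))
        root = logging.getLogger("qsprkit")
        root.addHandler(handler)
        root.setLevel(logging.INFO)
        root.propagate = False
    return logger


def log_counts(logger: logging.Logger, message: str, **counts: int) -> None:
    """Log ``message`` with a stable ``key=value`` rendering of the counts."""
    payload = " ".join(f"{k}={v}" for k, v in sorted(counts.items()))
    logger.info("%s %s", message, payload)
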