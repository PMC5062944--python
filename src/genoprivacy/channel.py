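"""Byte-counting message channel for the secure protocols.

Protocol messages (ciphertexts, secret shares, group elements) pass through a
:class:`Channel` whose transcript is append-only; the cumulative byte counts
per direction are the communication-cost measurements reported by the
evaluation harness.  The default transport is in-process and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Message", "Channel", "encode_uints", "decode_uints"]


@dataclass(frozen=True)
class Message:
    sender: str
    tag: str
    payload: bytes


@dataclass
class Channel:
    """Append-only transcript of (sender, payload) messages with cumulative
    per-sender byte counters."""

    transcript: list[Message] = field(default_factory=list)
    bytes_by_sender: dict[str, int] = field(default_factory=dict)
    _cursor: dict[str, int] = field(default_factory=dict)

    def send(self, sender: str, tag: str, payload: bytes) -> None:
        self.transcript.append(Message(sender, tag, bytes(payload)))
        self.bytes_by_sender[sender] = self.bytes_by_sender.get(sender, 0) + len(payload)

    def receive(self, receiver: str, expect_tag: str | None = None) -> Message:
        """Next unread message addressed to ``receiver`` (i.e. sent by the
        other party)."""
        pos = self._cursor.get(receiver, 0)
        while pos < len(self.transcript):
            msg = self.transcript[pos]
            pos += 1
            if msg.sender != receiver:
                self._cursor[receiver] = pos
                if expect_tag is not None and msg.tag != expect_tag:
                    raise RuntimeError(
                        f"protocol desync: expected {expect_tag!r}, got {msg.tag!r}"
                    )
                return msg
            self._cursor[receiver] = pos
        raise RuntimeError(f"no pending message for {receiver!r}")

    @property
    def total_bytes(self) -> int:
        return sum(self.bytes_by_sender.values())


def encode_uints(values, width: int) -> bytes:
    """Length-prefixed fixed-width big-endian unsigned integer vector."""
    out = bytearray(len(values).to_bytes(4, "big"))
    for v in values:
        out += int(v).to_bytes(width, "big")
    return bytes(out)


def decode_uints(payload: bytes, width: int) -> list[int]:
    n = int.from_bytes(payload[:4], "big")
    if len(payload) != 4 + n * width:
        raise ValueError("corrupt integer-vector payload")
    return [
        int.from_bytes(payload[4 + i * width : 4 + (i + 1) * width], "big")
        for i in range(n)
    ]
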