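"""Authenticated symmetric encryption for hub payloads.

AES-128 (FIPS-197) implemented from the specification, run in CTR mode, with
an HMAC-SHA256 tag in encrypt-then-MAC composition so that tampering and
wrong-key decryption are detected. Pure Python over the standard library;
payloads in this package are tens of bytes, so table-free round code is fast
enough. The block cipher is checked against the FIPS-197 known-answer vector
in the test suite.
"""

from __future__ import annotations

import hashlib
import hmac
import secrets

TAG_LEN = 16
NONCE_LEN = 12
KEY_LEN = 16


class AuthenticationError(ValueError):
    """Ciphertext failed integrity verification (tampered or wrong key)."""


def _build_sbox() -> bytes:
    # multiplicative inverse in GF(2^8) followed by the affine transform
    def gmul(a: int, b: int) -> int:
        r = 0
        for _ in range(8):
            if b & 1:
                r ^= a
            hi = a & 0x80
            a = (a << 1) & 0xFF
            if hi:
                a ^= 0x1B
            b >>= 1
        return r

    inv = [0] * 256
    for x in range(1, 256):
        for y in range(1, 256):
            if gmul(x, y) == 1:
                inv[x] = y
                break
    box = bytearray(256)
    for x in range(256):
        b = inv[x]
        box[x] = (
            b ^ ((b << 1) | (b >> 7)) ^ ((b << 2) | (b >> 6))
            ^ ((b << 3) | (b >> 5)) ^ ((b << 4) | (b >> 4)) ^ 0x63
        ) & 0xFF
    return bytes(box)


_SBOX = _build_sbox()
_RCON = (0x01, 0x02, 0x04, 0x08, 0x10, 0x20, 0x40, 0x80, 0x1B, 0x36)


def _xtime(a: int) -> int:
    a <<= 1
    return (a ^ 0x1B) & 0xFF if a & 0x100 else a


def _expand_key(key: bytes) -> list[bytes]:
    words = [key[i : i + 4] for i in range(0, 16, 4)]
    for i in range(4, 44):
        temp = words[i - 1]
        if i % 4 == 0:
            temp = bytes(_SBOX[b] for b in temp[1:] + temp[:1])
            temp = bytes((temp[0] ^ _RCON[i // 4 - 1],)) + temp[1:]
        words.append(bytes(a ^ b for a, b in zip(words[i - 4], temp)))
    return [b"".join(words[4 * r : 4 * r + 4]) for r in range(11)]


def encrypt_block(block: bytes, key: bytes) -> bytes:
    """AES-128 single-block encryption (16-byte block, 16-byte key)."""
    if len(block) != 16 or len(key) != KEY_LEN:
        raise ValueError("block and key must both be 16 bytes")
    round_keys = _expand_key(key)
    state = bytearray(a ^ b for a, b in zip(block, round_keys[0]))
    for rnd in range(1, 11):
        state = bytearray(_SBOX[b] for b in state)  # SubBytes
        # ShiftRows; state is column-major (state[4c+r]), row r rotates left by r
        state = bytearray(
            state[4 * ((c + r) % 4) + r] for c in range(4) for r in range(4)
        )
        if rnd != 10:  # MixColumns
            mixed = bytearray(16)
            for c in range(4):
                col = state[4 * c : 4 * c + 4]
                t = col[0] ^ col[1] ^ col[2] ^ col[3]
                for r in range(4):
                    mixed[4 * c + r] = col[r] ^ t ^ _xtime(col[r] ^ col[(r + 1) % 4])
            state = mixed
        state = bytearray(a ^ b for a, b in zip(state, round_keys[rnd]))
    return bytes(state)


def _keystream(key: bytes, nonce: bytes, n_bytes: int) -> bytes:
    out = bytearray()
    counter = 0
    while len(out) < n_bytes:
        out += encrypt_block(nonce + counter.to_bytes(4, "big"), key)
        counter += 1
    return bytes(out[:n_bytes])


def _derive(key: bytes) -> tuple[bytes, bytes]:
    if len(key) != KEY_LEN:
        raise ValueError(f"key must be {KEY_LEN} bytes, got {len(key)}")
    enc = hashlib.sha256(key + b"\x01enc").digest()[:16]
    mac = hashlib.sha256(key + b"\x02mac").digest()
    return enc, mac


def encrypt_payload(plaintext: bytes, key: bytes, nonce: bytes | None = None) -> bytes:
    """Encrypt and authenticate: returns nonce || ciphertext || tag."""
    enc_key, mac_key = _derive(key)
    if nonce is None:
        nonce = secrets.token_bytes(NONCE_LEN)
    if len(nonce) != NONCE_LEN:
        raise ValueError(f"nonce must be {NONCE_LEN} bytes")
    ct = bytes(
        a ^ b for a, b in zip(plaintext, _keystream(enc_key, nonce, len(plaintext)))
    )
    tag = hmac.new(mac_key, nonce + ct, hashlib.sha256).digest()[:TAG_LEN]
    return nonce + ct + tag


def decrypt_payload(blob: bytes, key: bytes) -> bytes:
    """Verify and decrypt; raises :class:`AuthenticationError` on any mismatch."""
    enc_key, mac_key = _derive(key)
    if len(blob) < NONCE_LEN + TAG_LEN:
        raise AuthenticationError("ciphertext too short")
    nonce, ct, tag = blob[:NONCE_LEN], blob[NONCE_LEN:-TAG_LEN], blob[-TAG_LEN:]
    expect = hmac.new(mac_key, nonce + ct, hashlib.sha256).digest()[:TAG_LEN]
    if not hmac.compare_digest(tag, expect):
        raise AuthenticationError("authentication tag mismatch")
    return bytes(a ^ b for a, b in zip(ct, _keystream(enc_key, nonce, len(ct))))
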