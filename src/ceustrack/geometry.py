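"""Axis-aligned bounding boxes and per-frame trajectories.

Conventions used throughout the package: image coordinates are (row, col),
0-based; boxes are half-open pixel intervals ``[row, row+height) x
[col, col+width)``; frame indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned pixel box ``[row, row+height) x [col, col+width)``."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 0 or self.width < 0:
            raise ValueError("box height/width must be nonnegative")

    @property
    def center(self) -> tuple[float, float]:
        """Continuous-coordinate center (row, col) of the covered pixel area."""
        return (self.row + self.height / 2.0, self.col + self.width / 2.0)

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def row_stop(self) -> int:
        return self.row + self.height

    @property
    def col_stop(self) -> int:
        return self.col + self.width

    def inside(self, frame_shape: tuple[int, int]) -> bool:
        return (
            self.row >= 0
            and self.col >= 0
            and self.row_stop <= frame_shape[0]
            and self.col_stop <= frame_shape[1]
        )

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row_stop), slice(self.col, self.col_stop)

    def shifted(self, drow: int, dcol: int) -> "BoundingBox":
        return BoundingBox(self.row + drow, self.col + dcol, self.height, self.width)

    @staticmethod
    def from_center(
        center: tuple[float, float], height: int, width: int
    ) -> "BoundingBox":
        """Integer box of given size whose center is nearest to ``center``."""
        row = int(round(center[0] - height / 2.0))
        col = int(round(center[1] - width / 2.0))
        return BoundingBox(row, col, height, width)

    def clipped(self, frame_shape: tuple[int, int]) -> "BoundingBox":
        """Translate the box (size preserved) so it lies inside the frame."""
        row = min(max(self.row, 0), frame_shape[0] - self.height)
        col = min(max(self.col, 0), frame_shape[1] - self.width)
        return BoundingBox(row, col, self.height, self.width)


def box_intersection_area(a: BoundingBox, b: BoundingBox) -> int:
    dr = min(a.row_stop, b.row_stop) - max(a.row, b.row)
    dc = min(a.col_stop, b.col_stop) - max(a.col, b.col)
    return max(dr, 0) * max(dc, 0)


@dataclass
class Trajectory:
    """Tracker output: one box (plus center and classifier score) per frame."""

    boxes: list[BoundingBox] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)

    def append(self, box: BoundingBox, score: float = float("nan")) -> None:
        self.boxes.append(box)
        self.scores.append(float(score))

    def __len__(self) -> int:
        return len(self.boxes)

    @property
    def centers(self) -> np.ndarray:
        """(n_frames, 2) array of (row, col) box centers."""
        return np.asarray([b.center for b in self.boxes], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.boxes)),
                "row": [b.row for b in self.boxes],
                "col": [b.col for b in self.boxes],
                "height": [b.height for b in self.boxes],
                "width": [b.width for b in self.boxes],
                "score": self.scores,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "Trajectory":
        df = pd.read_csv(path)
        traj = Trajectory()
        for rec in df.itertuples(index=False):
            traj.append(
                BoundingBox(int(rec.row), int(rec.col), int(rec.height), int(rec.width)),
                float(getattr(rec, "score", float("nan"))),
            )
        return traj
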