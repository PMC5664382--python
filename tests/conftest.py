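import numpy as np
import pytest

import facecolor as fc


@pytest.fixture(scope="session")
def target_chart():
    return fc.make_target_chart()


@pytest.fixture(scope="session")
def chart(target_chart):
    """(flat chart image, layout) rendered from the nominal target table."""
    return fc.render_chart_image(target_chart)


@pytest.fixture(scope="session")
def face():
    """Default schematic face: (image, landmarks, region truth, part colors)."""
    return fc.render_synthetic_face()


@pytest.fixture(scope="session")
def face_masks(face):
    _, landmarks, _, _ = face
    return fc.build_masks(landmarks)


@pytest.fixture(scope="session")
def face_skin_model(face):
    """Histogram model trained on the render's flat part colors."""
    _, _, _, parts = face
    pix = fc.labeled_pixels_for_face(parts)
    skin = pix.loc[pix.label == "skin", ["R", "G", "B"]].to_numpy()
    nonskin = pix.loc[pix.label == "nonskin", ["R", "G", "B"]].to_numpy()
    return fc.train_skin_model(skin, nonskin)


@pytest.fixture(scope="session")
def face_lab_records(face, face_masks, face_skin_model):
    """Feature records extracted end-to-end from the default face."""
    image, _, _, _ = face
    lab = fc.rgb_to_lab(image)
    skin = fc.classify_image(image, face_skin_model)
    return fc.extract_region_colors(lab, face_masks, skin, "fixture")
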