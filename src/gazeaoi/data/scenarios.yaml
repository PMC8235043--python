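# Per-scenario mappings from vision-model class labels to AOI names.
# "ic" uses ImageNet labels, "od" uses MS COCO labels.  AOIs listed under
# "unmapped" have no usable class label for that method and are expected
# to fail by design.
scenarios:
  "01-car pursuit":
    aois: ["red car", "white car"]
    ic:
      labels:
        streetcar: "red car"
        sports car: "red car"
        minivan: "red car"
        cab: "red car"
        minibus: "red car"
        limousine: "red car"
        car mirror: "red car"
        racer: "red car"
        passenger car: "red car"
      unmapped: ["white car"]
    od:
      labels:
        car: "red car"
      unmapped: ["white car"]
  "02-turning car":
    aois: ["red car"]
    ic:
      labels:
        streetcar: "red car"
        sports car: "red car"
        minivan: "red car"
        cab: "red car"
        minibus: "red car"
        limousine: "red car"
        car mirror: "red car"
        racer: "red car"
        passenger car: "red car"
      unmapped: []
    od:
      labels:
        car: "red car"
      unmapped: []
  "03-dialog":
    aois: ["left face", "right face", "shirt"]
    ic:
      labels:
        ear: "left face"
        sweatshirt: "shirt"
      unmapped: ["right face"]
    od:
      labels:
        person: "left face"
      unmapped: ["right face", "shirt"]
  "04-thimblerig":
    aois: ["cup1", "cup2", "cup3"]
    ic:
      labels:
        cocktail shaker: "cup1"
        coffee mug: "cup1"
        cup: "cup1"
      unmapped: ["cup2", "cup3"]
    od:
      labels:
        cup: "cup1"
        bowl: "cup2"
      unmapped: ["cup3"]
  "05-memory":
    aois: ["cards"]
    ic:
      labels:
        desk: "cards"
      unmapped: []
    od:
      labels:
        dining table: "cards"
      unmapped: []
  "06-UNO":
    aois: ["left hand", "right hand", "stack covered", "stack uncovered"]
    ic:
      labels:
        desk: "stack covered"
      unmapped: ["left hand", "right hand", "stack uncovered"]
    od:
      labels:
        person: "left hand"
        dining table: "stack covered"
      unmapped: ["right hand", "stack uncovered"]
  "07-kite":
    aois: ["person", "kite"]
    ic:
      labels:
        lab coat: "person"
        poncho: "person"
        cardigan: "person"
        cloak: "person"
        sweatshirt: "person"
        trench coat: "person"
        balloon: "kite"
        kite: "kite"
        parachute: "kite"
      unmapped: []
    od:
      labels:
        person: "person"
        kite: "kite"
      unmapped: []
  "08-case exchange":
    aois: ["persons", "textbox", "case", "suspects"]
    ic:
      labels:
        sombrero: "persons"
        cowboy hat: "persons"
        mailbag: "case"
        packet: "case"
        plastic bag: "case"
        shopping basket: "case"
        backpack: "case"
        bucket: "case"
        crate: "case"
        lab coat: "suspects"
        poncho: "suspects"
        cardigan: "suspects"
        cloak: "suspects"
        sweatshirt: "suspects"
        trench coat: "suspects"
      unmapped: ["textbox"]
    od:
      labels:
        person: "persons"
        handbag: "case"
        suitcase: "case"
      unmapped: ["textbox", "suspects"]
  "09-ball game":
    aois: ["ball", "player white", "player red1", "player red2", "player red3"]
    ic:
      labels:
        baseball: "ball"
        basketball: "ball"
        rugby ball: "ball"
        tennis ball: "ball"
        volleyball: "ball"
        soccer ball: "ball"
        ballplayer: "player white"
      unmapped: ["player red1", "player red2", "player red3"]
    od:
      labels:
        sports ball: "ball"
        person: "player white"
      unmapped: ["player red1", "player red2", "player red3"]
  "10-bag search":
    aois: ["red bag", "yellow bag", "blue bag", "red-white bag", "brown bag", "persons"]
    ic:
      labels:
        plastic bag: "red bag"
        mailbag: "brown bag"
        lab coat: "persons"
        poncho: "persons"
        cardigan: "persons"
        cloak: "persons"
        sweatshirt: "persons"
        trench coat: "persons"
      unmapped: ["yellow bag", "blue bag", "red-white bag"]
    od:
      labels:
        handbag: "red bag"
        person: "persons"
      unmapped: ["yellow bag", "blue bag", "red-white bag", "brown bag"]
  "11-person search":
    aois: ["hooded", "red shirt and hat", "persons"]
    ic:
      labels:
        lab coat: "hooded"
        poncho: "hooded"
        cardigan: "hooded"
        cloak: "hooded"
        sweatshirt: "hooded"
        trench coat: "hooded"
        sombrero: "red shirt and hat"
        cowboy hat: "red shirt and hat"
      unmapped: ["persons"]
    od:
      labels:
        person: "hooded"
      unmapped: ["red shirt and hat", "persons"]
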