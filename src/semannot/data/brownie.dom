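; Toy "Brownie" kitchen domain: 11 action classes
; (open close take put walk turn_on fill clean stir shake other)
; over a small entity set drawn from the published annotation vocabulary.
;
; Modelling conventions:
;  - discrete takeables have a conserved location fluent is-at;
;  - countable items (egg shells) are manipulated with an integer
;    multiplicity token in the label (take-1-egg_shell-...); only the hand
;    capacity (objects_taken, max 3) is tracked for them, not per-location
;    counts, which matches the observed annotation granularity;
;  - cracking a shell is its own zero-parameter schema of class "open";
;  - emptying a cracked shell is a fill variant with the literal token
;    open_egg_shell in its label.
(define (domain brownie)
  (:types location takeable pourable countable count place - object
          fixture hand - location
          storage surface device - fixture
          vessel - takeable)
  (:objects cupboard_tl cupboard_tr cupboard_br cupboard_bl fridge egg_box - storage
            counter sink - surface
            stove - device
            hands - hand
            counter_place fridge_place stove_place - place
            brownie_box bowl measuring_cup_s measuring_cup_l oil_bottle butter_pack baking_pan tap egg_tray - vessel
            egg water oil brownie_mix butter - pourable
            egg_shell open_egg_shell empty_egg_shell - countable
            1 2 - count)
  (:functions (is-at ?w - takeable) - location
              (is-in ?p - pourable) - vessel
              (is-open ?s - storage) - boolean
              (is-on ?d - device) - boolean
              (place-of ?f - fixture) - place
              (objects_taken) - number
              (at) - place)
  (:init (= (is-at brownie_box) cupboard_tl)
         (= (is-at bowl) cupboard_tr)
         (= (is-at measuring_cup_s) cupboard_tr)
         (= (is-at measuring_cup_l) cupboard_tr)
         (= (is-at oil_bottle) cupboard_br)
         (= (is-at baking_pan) cupboard_bl)
         (= (is-at butter_pack) fridge)
         (= (is-at tap) sink)
         (= (is-at egg_tray) fridge)
         (= (is-in egg) egg_tray)
         (= (is-in water) tap)
         (= (is-in oil) oil_bottle)
         (= (is-in brownie_mix) brownie_box)
         (= (is-in butter) butter_pack)
         (= (place-of cupboard_tl) counter_place)
         (= (place-of cupboard_tr) counter_place)
         (= (place-of cupboard_br) counter_place)
         (= (place-of cupboard_bl) counter_place)
         (= (place-of fridge) fridge_place)
         (= (place-of egg_box) fridge_place)
         (= (place-of counter) counter_place)
         (= (place-of sink) counter_place)
         (= (place-of stove) stove_place)
         (= (objects_taken) 0)
         (= (at) counter_place))
  (:action open
    :parameters (?s - storage)
    :precondition (and (not (is-open ?s)) (= (at) (place-of ?s)))
    :effect (assign (is-open ?s) true)
    :label "open-{s}")
  (:action close
    :parameters (?s - storage)
    :precondition (and (is-open ?s) (= (at) (place-of ?s)))
    :effect (assign (is-open ?s) false)
    :label "close-{s}")
  (:action open
    ; crack an egg shell held in the hand
    :parameters ()
    :precondition (> (objects_taken) 0)
    :effect (and)
    :label "open-egg_shell")
  (:action take
    :parameters (?what - takeable ?from - storage)
    :precondition (and (= (is-at ?what) ?from) (is-open ?from)
                       (= (at) (place-of ?from)) (< (objects_taken) 3))
    :effect (and (assign (is-at ?what) hands) (increase (objects_taken) 1))
    :label "take-{what}-{from}")
  (:action take
    :parameters (?what - takeable ?from - surface)
    :precondition (and (= (is-at ?what) ?from)
                       (= (at) (place-of ?from)) (< (objects_taken) 3))
    :effect (and (assign (is-at ?what) hands) (increase (objects_taken) 1))
    :label "take-{what}-{from}")
  (:action put
    :parameters (?what - takeable ?to - storage)
    :precondition (and (= (is-at ?what) hands) (is-open ?to)
                       (= (at) (place-of ?to)) (>= (objects_taken) 1))
    :effect (and (assign (is-at ?what) ?to) (decrease (objects_taken) 1))
    :label "put-{what}-{to}")
  (:action put
    :parameters (?what - takeable ?to - surface)
    :precondition (and (= (is-at ?what) hands)
                       (= (at) (place-of ?to)) (>= (objects_taken) 1))
    :effect (and (assign (is-at ?what) ?to) (decrease (objects_taken) 1))
    :label "put-{what}-{to}")
  (:action take
    :parameters (?n - count ?what - countable ?from - storage)
    :precondition (and (is-open ?from) (= (at) (place-of ?from))
                       (< (objects_taken) 3))
    :effect (increase (objects_taken) ?n)
    :label "take-{n}-{what}-{from}")
  (:action take
    :parameters (?n - count ?what - countable ?from - surface)
    :precondition (and (= (at) (place-of ?from)) (< (objects_taken) 3))
    :effect (increase (objects_taken) ?n)
    :label "take-{n}-{what}-{from}")
  (:action put
    :parameters (?n - count ?what - countable ?to - surface)
    :precondition (and (= (at) (place-of ?to)) (>= (objects_taken) ?n))
    :effect (decrease (objects_taken) ?n)
    :label "put-{n}-{what}-{to}")
  (:action walk
    :parameters (?from - place ?to - place)
    :precondition (and (= (at) ?from) (not (= ?from ?to)))
    :effect (assign (at) ?to)
    :label "walk-{from}-{to}")
  (:action turn_on
    :parameters (?d - device)
    :precondition (and (not (is-on ?d)) (= (at) (place-of ?d)))
    :effect (assign (is-on ?d) true)
    :label "turn_on-{d}")
  (:action fill
    :parameters (?stuff - pourable ?from - vessel ?to - vessel)
    :precondition (and (= (is-in ?stuff) ?from) (not (= ?from ?to)))
    :effect (assign (is-in ?stuff) ?to)
    :label "fill-{stuff}-{from}-{to}")
  (:action fill
    ; empty a cracked egg shell (held) into a vessel
    :parameters (?stuff - pourable ?to - vessel)
    :precondition (> (objects_taken) 0)
    :effect (assign (is-in ?stuff) ?to)
    :label "fill-{stuff}-open_egg_shell-{to}")
  (:action clean
    :parameters (?what - takeable)
    :precondition (= (is-at ?what) hands)
    :effect (and)
    :label "clean-{what}")
  (:action stir
    :parameters (?v - vessel)
    :precondition (not (= (is-at ?v) hands))
    :effect (and)
    :label "stir-{v}")
  (:action shake
    :parameters (?what - takeable)
    :precondition (= (is-at ?what) hands)
    :effect (and)
    :label "shake-{what}")
  (:action other
    :parameters ()
    :precondition (and)
    :effect (and)
    :label "other")
)
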