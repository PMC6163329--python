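; Minimal kitchen domain: one takeable, three surfaces, a hand-capacity
; counter capped at 3 simultaneously held objects.
(define (domain toy-kitchen)
  (:types takeable location place - object
          surface hand - location)
  (:objects knife - takeable
            drawer counter board - surface
            hands - hand
            kitchen - place)
  (:functions (is-at ?what - takeable) - location
              (objects_taken) - number
              (at) - place)
  (:init (= (is-at knife) drawer)
         (= (objects_taken) 0)
         (= (at) kitchen))
  (:action take
    :parameters (?what - takeable ?from - surface)
    :precondition (and (= (is-at ?what) ?from)
                       (< (objects_taken) 3))
    :effect (and (assign (is-at ?what) hands)
                 (increase (objects_taken) 1))
    :label "take-{what}-{from}")
  (:action put
    :parameters (?what - takeable ?to - surface)
    :precondition (and (= (is-at ?what) hands)
                       (>= (objects_taken) 1))
    :effect (and (assign (is-at ?what) ?to)
                 (decrease (objects_taken) 1))
    :label "put-{what}-{to}")
  (:action walk
    :parameters (?from - place ?to - place)
    :precondition (and (= (at) ?from) (not (= ?from ?to)))
    :effect (assign (at) ?to)
    :label "walk-{from}-{to}")
  (:action stir
    :parameters (?what - takeable)
    :precondition (= (is-at ?what) hands)
    :effect (and)
    :label "stir-{what}")
)
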