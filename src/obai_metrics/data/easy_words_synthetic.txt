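# Synthetic easy-word list (Dale-Chall style): a constructed list of common
# English words bundled as the default "easy words" resource. It is NOT the
# published 3000-word list; supply your own list via --easy-words / easy_words
# for scoring against the canonical resource.
a
about
above
across
after
afternoon
again
against
age
ago
air
all
almost
alone
along
already
also
always
am
an
and
animal
another
answer
any
anyone
anything
apple
are
arm
around
as
ask
asked
at
ate
away
baby
back
bad
bag
ball
banana
bark
barked
basket
be
bear
beautiful
beautifully
became
because
become
bed
bedroom
been
before
began
begin
behind
being
bell
belong
below
bench
beside
best
better
between
big
bird
birds
birthday
bit
black
blue
boat
boats
body
book
books
both
bottle
bowl
box
boy
boys
bread
break
breakfast
bridge
bright
bring
brother
brought
brown
build
built
bus
busy
but
butter
buy
by
cake
call
called
came
can
candy
cap
car
card
care
carry
cars
cat
caterpillar
cats
catch
caught
chair
chance
change
chicken
child
children
city
class
clean
climb
clock
close
cloth
cloud
coat
cold
color
come
cook
cooked
cool
corn
corner
could
country
cover
cow
cried
cry
cup
cut
dance
danced
dark
day
days
dear
deep
did
dig
dinner
dish
do
doctor
does
dog
dogs
done
door
down
draw
dream
dress
drink
drive
drop
dry
duck
during
each
ear
early
earth
east
easy
eat
eaten
egg
eggs
eight
either
elephant
eleven
else
empty
end
enough
even
evening
ever
every
everyone
everything
eye
eyes
face
fall
family
fancy
far
farm
farmer
fast
fat
father
feed
feel
feet
fell
felt
fence
few
field
fifth
fill
find
fine
finger
finish
fire
first
fish
five
fix
floor
flower
flowers
fly
follow
food
foot
for
forest
forget
found
four
fox
free
fresh
friend
friends
frog
from
front
fruit
full
fun
funny
game
games
garden
gate
gave
gentle
get
girl
girls
give
given
glad
glass
go
goat
goes
going
gold
golden
gone
good
got
grand
grass
gray
great
green
grew
ground
grow
grown
had
hair
half
hand
hands
happy
hard
has
hat
have
having
hay
he
head
hear
heard
heart
held
hello
help
helped
hen
her
here
hers
herself
hid
hide
high
hill
him
himself
his
hold
hole
holiday
home
hop
hope
horse
hot
hour
house
houses
how
hundred
hungry
hurry
hurt
i
ice
if
in
inside
into
is
it
its
itself
jump
jumped
just
keep
kept
kind
king
kitchen
kite
kitten
knew
know
known
lady
lake
land
large
last
late
laugh
lay
learn
leave
left
leg
let
letter
light
like
liked
line
lion
listen
little
live
lived
long
look
looked
lost
lot
loud
love
loved
low
lunch
made
make
man
many
market
mat
may
me
meal
mean
meet
men
met
middle
might
milk
mine
minute
miss
moment
money
monkey
moon
more
morning
most
mother
mountain
mouse
mouth
move
much
music
must
my
myself
name
near
neck
need
nest
never
new
next
nice
night
nine
no
noise
north
nose
not
note
nothing
now
number
nut
of
off
often
oh
old
on
once
one
only
open
opened
or
orange
other
our
ours
out
outside
over
own
page
paint
painted
pair
pan
paper
park
part
party
pass
past
paw
pay
pen
penny
people
pet
pick
picked
picnic
picture
pie
piece
pig
place
plan
plant
play
played
please
pocket
point
pond
pony
poor
potato
pretty
pull
puppy
purple
purr
purred
push
put
queen
quick
quickly
quiet
rabbit
race
rain
ran
reach
read
ready
red
rest
ride
right
ring
river
road
rock
roll
roof
room
rope
round
run
sad
said
same
sand
sang
sat
saw
say
school
sea
seat
second
see
seed
seen
sees
send
sent
seven
shall
she
sheep
shine
ship
shoe
shop
short
should
show
sick
side
silver
simple
sing
sister
sit
six
sky
sleep
sleeps
slept
slow
slowly
small
smile
snow
so
soft
some
someone
something
song
soon
sound
soup
south
spoke
spot
spring
squirrel
stand
star
stars
start
stay
step
stick
still
stone
stood
stop
stopped
store
story
street
strong
summer
sun
sunny
supper
sure
sweet
swim
table
tail
take
taken
takes
talk
talked
tall
teacher
tell
ten
than
thank
that
the
their
theirs
them
themselves
then
there
these
they
thing
things
think
third
this
those
thought
three
threw
through
throw
thrown
tidy
time
tiny
tired
to
today
together
told
tomorrow
too
took
top
town
toy
toys
train
tree
trees
tried
truck
try
turn
turtle
twelve
twenty
twice
two
under
until
up
upon
us
use
used
very
visit
wait
walk
walked
wall
want
wanted
warm
was
wash
watch
water
watermelon
wave
way
we
wear
weather
week
well
went
were
wet
what
wheel
when
where
which
while
white
who
whole
whose
why
wide
will
win
wind
window
windows
winter
wish
with
within
without
woman
women
wonder
wonderful
wood
word
words
work
world
would
write
yard
year
years
yellow
yes
yesterday
yet
you
young
your
yours
yourself
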